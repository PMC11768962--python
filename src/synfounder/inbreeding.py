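"""Inbreeding coefficient of a synthetic variety from finite founder samples.

A synthetic is formed by randomly mating m plants from each of l
unrelated parental lines with inbreeding coefficient F.  The m plants
of one line are organised as g = floor(m/4) complete groups — each
containing one plant of every GA4 genotype — plus e = m mod 4 leftover
plants of distinct genotypes.  Averaging the progeny inbreeding
coefficients over all m^2 ordered within-line matings (selfings
included) and dividing by l gives

    F_SynL = [ m(3+F)/4 + (12g + e(e-1))(5+7F)/12
               + (16g(g-1) + 8ge)(1+F)/2 ] / (m^2 l).

As m grows the per-line value l*F_SynL converges to the Hardy-Weinberg
limit (1+F)/2, reached exactly whenever m is a multiple of 4.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import pandas as pd

from ._rounding import round_half_away
from .genetic_model import (
    _check_f,
    mean_between_group_ic,
    mean_selfing_ic,
    mean_within_group_cross_ic,
)

__all__ = [
    "SampleDesign",
    "SyntheticICResult",
    "decompose_sample",
    "synthetic_ic",
    "ic_table",
    "ic_grid_exact",
    "asymptote",
    "DEFAULT_F_VALUES",
]

#: line-inbreeding levels used for the reference grid
DEFAULT_F_VALUES: tuple[Fraction, ...] = (
    Fraction(0),
    Fraction(1, 2),
    Fraction(3, 4),
    Fraction(7, 8),
    Fraction(1),
)


@dataclass(frozen=True)
class SampleDesign:
    """Decomposition of a line's sample into complete 4-plant groups.

    Invariant: ``m == 4 * g + e`` with ``e`` in {0, 1, 2, 3}.
    """

    m: int
    g: int
    e: int

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"sample size m must be >= 1, got {self.m}")
        if self.m != 4 * self.g + self.e or not (0 <= self.e <= 3):
            raise ValueError("inconsistent (m, g, e) decomposition")


def decompose_sample(m: int) -> SampleDesign:
    """Split m plants into g complete 4-plant groups and e leftovers."""
    if m < 1:
        raise ValueError(f"sample size m must be >= 1, got {m}")
    g, e = divmod(m, 4)
    return SampleDesign(m=m, g=g, e=e)


@dataclass(frozen=True)
class SyntheticICResult:
    """Exact inbreeding of the synthetic and its per-line (l=1) scale."""

    m: int
    F: Fraction
    l: int
    f_syn_l: Fraction
    per_line_value: Fraction

    @property
    def design(self) -> SampleDesign:
        return decompose_sample(self.m)


def synthetic_ic(m: int, F, l: int = 1) -> SyntheticICResult:
    """Exact inbreeding coefficient F_SynL of the synthetic variety.

    Parameters
    ----------
    m : plants sampled per parental line (>= 1).
    F : inbreeding coefficient of the parental lines, in [0, 1].
    l : number of unrelated parental lines (>= 1).
    """
    F = _check_f(F)
    if l < 1:
        raise ValueError(f"number of lines l must be >= 1, got {l}")
    d = decompose_sample(m)
    g, e = d.g, d.e
    numerator = (
        m * mean_selfing_ic(F)
        + (12 * g + e * (e - 1)) * mean_within_group_cross_ic(F)
        + (16 * g * (g - 1) + 8 * g * e) * mean_between_group_ic(F)
    )
    per_line = numerator / (m * m)
    return SyntheticICResult(m=m, F=F, l=l, f_syn_l=per_line / l, per_line_value=per_line)


def asymptote(F) -> Fraction:
    """Large-m per-line limit of the inbreeding coefficient: (1+F)/2.

    Divide by l for the synthetic itself.
    """
    return mean_between_group_ic(F)


def ic_grid_exact(
    m_values: Sequence[int], F_values: Sequence = DEFAULT_F_VALUES
) -> dict[tuple[int, Fraction], Fraction]:
    """Exact per-line values over an m x F grid, keyed by (m, F)."""
    return {
        (m, Fraction(F)): synthetic_ic(m, F).per_line_value
        for m in m_values
        for F in F_values
    }


def ic_table(
    m_values: Sequence[int] | None = None,
    F_values: Sequence = DEFAULT_F_VALUES,
    decimals: int = 2,
) -> pd.DataFrame:
    """Reference grid of per-line values l*F_SynL, rounded for display.

    Defaults (m = 1..24, F in {0, 0.5, 0.75, 0.875, 1}) reproduce the
    standard published grid; rounding is half-away-from-zero.  Columns:
    ``m``, ``e``, then one column per F level.
    """
    if m_values is None:
        m_values = range(1, 25)
    F_values = [Fraction(F) for F in F_values]
    grid = ic_grid_exact(list(m_values), F_values)
    rows = []
    for m in m_values:
        row: dict[str, object] = {"m": m, "e": decompose_sample(m).e}
        for F in F_values:
            row[f"F={float(F):g}"] = float(round_half_away(grid[(m, F)], decimals))
        rows.append(row)
    return pd.DataFrame(rows)
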
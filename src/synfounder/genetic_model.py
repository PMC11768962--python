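"""Single-locus genetic model of a selfed parental line.

A parental line of genotype A1A2 is selfed; its progeny follow the
genotypic array

    GA4 = 1/4 A1A1 + 1/4 A1A2 + 1/4 A2A1 + 1/4 A2A2,

where the two heterozygote orderings are kept distinct because they are
distinct sampling outcomes.  Merging them gives the collapsed array
GA3 = (1/4, 1/2, 1/4).  The line's own inbreeding coefficient F is the
probability that its two alleles A1 and A2 are identical by descent
(IBD); every identity coefficient downstream is a linear form a + b*F.

All arithmetic in this module is exact: probabilities are
:class:`fractions.Fraction` and identity coefficients are
:class:`LinearIC` forms.  Floats never appear.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

__all__ = [
    "Genotype",
    "GenotypicArray",
    "LinearIC",
    "LineParams",
    "MatingICTable",
    "selfed_line_array",
    "collapse_to_ga3",
    "progeny_ic_form",
    "progeny_ic",
    "mean_selfing_ic",
    "mean_within_group_cross_ic",
    "mean_between_group_ic",
    "mating_ic_table",
]

#: shorthand rationals used throughout
_F0 = Fraction(0)
_F1 = Fraction(1)


class Genotype(enum.Enum):
    """One of the four ordered single-locus genotypes of the line's progeny.

    The pair is ordered (maternal, paternal): ``A1A2`` and ``A2A1`` are
    distinct members even though they are genetically identical.
    """

    A1A1 = ("A1", "A1")
    A1A2 = ("A1", "A2")
    A2A1 = ("A2", "A1")
    A2A2 = ("A2", "A2")

    @property
    def allele_a(self) -> str:
        return self.value[0]

    @property
    def allele_b(self) -> str:
        return self.value[1]

    @property
    def is_homozygous(self) -> bool:
        return self.value[0] == self.value[1]

    @property
    def label(self) -> str:
        return self.value[0] + self.value[1]


#: canonical GA4 genotype order
GA4_ORDER: tuple[Genotype, ...] = (
    Genotype.A1A1,
    Genotype.A1A2,
    Genotype.A2A1,
    Genotype.A2A2,
)

#: canonical GA3 genotype labels (heterozygotes merged)
GA3_LABELS: tuple[str, ...] = ("A1A1", "A1A2", "A2A2")


@dataclass(frozen=True)
class GenotypicArray:
    """Labelled genotype classes with exact probabilities.

    ``arity`` 4 is the full selfed-progeny array (1/4 each); arity 3 is
    the collapsed form with the heterozygotes merged (1/4, 1/2, 1/4).
    """

    labels: tuple[str, ...]
    probabilities: tuple[Fraction, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.probabilities):
            raise ValueError("labels and probabilities must align")
        if any(p < 0 for p in self.probabilities):
            raise ValueError("probabilities must be nonnegative")
        if sum(self.probabilities, _F0) != 1:
            raise ValueError("probabilities must sum exactly to 1")

    @property
    def arity(self) -> int:
        return len(self.labels)


def selfed_line_array() -> GenotypicArray:
    """Genotypic array of the progeny of selfing a heterozygous line.

    Each of the four ordered genotypes occurs with probability 1/4.
    """
    q = Fraction(1, 4)
    return GenotypicArray(
        labels=tuple(g.label for g in GA4_ORDER),
        probabilities=(q, q, q, q),
    )


def collapse_to_ga3(ga4: GenotypicArray) -> GenotypicArray:
    """Merge the two heterozygote classes of a 4-class array.

    Returns the 3-class array ordered (A1A1, A1A2, A2A2); with the
    selfed-line array the result is (1/4, 1/2, 1/4).
    """
    if ga4.arity != 4:
        raise ValueError(f"expected a 4-class array, got arity {ga4.arity}")
    p = dict(zip(ga4.labels, ga4.probabilities))
    return GenotypicArray(
        labels=GA3_LABELS,
        probabilities=(p["A1A1"], p["A1A2"] + p["A2A1"], p["A2A2"]),
    )


@dataclass(frozen=True)
class LinearIC:
    """An identity coefficient as the exact linear form ``a + b*F``."""

    a: Fraction
    b: Fraction

    def __call__(self, F: Fraction | int) -> Fraction:
        F = _check_f(F)
        return self.a + self.b * F

    def __add__(self, other: "LinearIC") -> "LinearIC":
        return LinearIC(self.a + other.a, self.b + other.b)

    def scale(self, c) -> "LinearIC":
        c = Fraction(c)
        return LinearIC(self.a * c, self.b * c)


def _check_f(F) -> Fraction:
    F = Fraction(F)
    if not (0 <= F <= 1):
        raise ValueError(f"inbreeding coefficient F must lie in [0, 1], got {F}")
    return F


@dataclass(frozen=True)
class LineParams:
    """Parameters of the founder panel: line inbreeding F and line count l."""

    F: Fraction
    l: int

    def __post_init__(self) -> None:
        _check_f(self.F)
        if self.l < 1:
            raise ValueError(f"number of lines l must be >= 1, got {self.l}")


def progeny_ic_form(p1: Genotype, p2: Genotype) -> LinearIC:
    """Inbreeding coefficient of the progeny of mating ``p1 x p2``.

    Both parents are progeny of the same line A1A2 whose alleles are IBD
    with probability F.  Selfing a homozygote gives 1; crossing the two
    opposite homozygotes gives F (the progeny's alleles are the line's
    original A1 and A2); every other mating, including selfing a
    heterozygote, gives (1+F)/2.
    """
    if p1 is p2 and p1.is_homozygous:
        return LinearIC(_F1, _F0)
    if p1.is_homozygous and p2.is_homozygous and p1 is not p2:
        return LinearIC(_F0, _F1)
    return LinearIC(Fraction(1, 2), Fraction(1, 2))


def progeny_ic(p1: Genotype, p2: Genotype, F) -> Fraction:
    """Evaluate :func:`progeny_ic_form` at a given F (exact)."""
    return progeny_ic_form(p1, p2)(F)


def mean_selfing_ic(F) -> Fraction:
    """Average IC of the 4 selfings of one complete group: (3+F)/4."""
    F = _check_f(F)
    return (3 + F) / 4


def mean_within_group_cross_ic(F) -> Fraction:
    """Average IC of the 12 ordered crosses within a group: (5+7F)/12.

    A complete group contains one plant of each of the four GA4
    genotypes, so its crosses are the 12 ordered pairs of *distinct*
    genotypes.
    """
    F = _check_f(F)
    return (5 + 7 * F) / 12


def mean_between_group_ic(F) -> Fraction:
    """Average IC over all 16 ordered genotype pairs: (1+F)/2.

    This is the between-group (and generally the independent-genotype)
    mating average, and the Hardy-Weinberg limit of the synthetic's
    inbreeding per line.
    """
    F = _check_f(F)
    return (1 + F) / 2


@dataclass(frozen=True)
class MatingICTable:
    """The 4x4 table of progeny ICs over ordered GA4 parent pairs.

    Entries are exact linear forms in F; the row, column and global
    means all reduce to (1+F)/2.
    """

    entries: dict[tuple[Genotype, Genotype], LinearIC]

    def row_mean(self, p1: Genotype) -> LinearIC:
        return _mean(self.entries[(p1, p2)] for p2 in GA4_ORDER)

    def col_mean(self, p2: Genotype) -> LinearIC:
        return _mean(self.entries[(p1, p2)] for p1 in GA4_ORDER)

    def global_mean(self) -> LinearIC:
        return _mean(self.entries.values())

    def selfing_mean(self) -> LinearIC:
        return _mean(self.entries[(g, g)] for g in GA4_ORDER)

    def cross_mean(self) -> LinearIC:
        return _mean(
            self.entries[(g1, g2)]
            for g1 in GA4_ORDER
            for g2 in GA4_ORDER
            if g1 is not g2
        )


def _mean(forms: Iterable[LinearIC]) -> LinearIC:
    forms = list(forms)
    total = LinearIC(_F0, _F0)
    for f in forms:
        total = total + f
    return total.scale(Fraction(1, len(forms)))


def mating_ic_table() -> MatingICTable:
    """Build the full table of progeny ICs for all 16 ordered matings."""
    return MatingICTable(
        entries={
            (p1, p2): progeny_ic_form(p1, p2)
            for p1 in GA4_ORDER
            for p2 in GA4_ORDER
        }
    )
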
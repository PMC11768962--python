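"""Allele-level consequences of finite founder sampling.

Three exact quantities for a size-m sample drawn from the selfed-line
array GA4:

* the probability an allele is lost outright (the sample is all A1A1
  or all A2A2): ``2 (1/4)^m``;
* the probability the sample preserves the line's 1:1 allele ratio,
  computed by enumerating genotype count vectors (and, as an
  independent identity, equal to ``C(2m, m) / 4^m``);
* the inbreeding coefficient of the progeny a given sample would
  produce under random mating, as the linear form
  ``(p^2 + q^2) + 2pq F`` in the line inbreeding F.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction
from math import comb

from .genetic_model import LinearIC, _check_f, selfed_line_array
from .retention import multinomial_mass

__all__ = [
    "SampleCounts",
    "ProgenyIC",
    "gene_loss_probability",
    "equal_allele_freq_probability",
    "equal_allele_freq_closed_form",
    "progeny_ic_from_sample",
]


@dataclass(frozen=True)
class SampleCounts:
    """Genotype counts of one sample, in GA4 order."""

    n_a1a1: int
    n_a1a2: int
    n_a2a1: int
    n_a2a2: int

    def __post_init__(self) -> None:
        if min(self.as_tuple()) < 0:
            raise ValueError("genotype counts must be nonnegative")
        if self.m < 1:
            raise ValueError("sample must contain at least one plant")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.n_a1a1, self.n_a1a2, self.n_a2a1, self.n_a2a2)

    @property
    def m(self) -> int:
        return sum(self.as_tuple())

    @property
    def n_allele_a1(self) -> int:
        return 2 * self.n_a1a1 + self.n_a1a2 + self.n_a2a1

    @property
    def n_allele_a2(self) -> int:
        return 2 * self.m - self.n_allele_a1

    @property
    def p_a1(self) -> Fraction:
        return Fraction(self.n_allele_a1, 2 * self.m)


@dataclass(frozen=True)
class ProgenyIC:
    """IC of the random-mating progeny of a sample: ``a + b*F``.

    ``a = p^2 + q^2`` and ``b = 2pq`` with p, q the sample allele
    frequencies; a + b = 1 and a >= 1/2 with equality iff p = q = 1/2.
    """

    a: Fraction
    b: Fraction
    p: Fraction
    q: Fraction

    def form(self) -> LinearIC:
        return LinearIC(self.a, self.b)

    def __call__(self, F) -> Fraction:
        return self.form()(F)


def gene_loss_probability(m: int) -> Fraction:
    """Probability a size-m sample loses A1 or A2 entirely: 2 (1/4)^m.

    Loss requires the whole sample to be the same homozygote; any
    heterozygote carries both alleles, so only the all-A1A1 and
    all-A2A2 samples qualify (the same on GA4 and GA3).
    """
    if m < 1:
        raise ValueError(f"sample size m must be >= 1, got {m}")
    return 2 * Fraction(1, 4) ** m


def _iter_count_vectors(m: int):
    """All ordered 4-part nonnegative count vectors summing to m."""
    for a in range(m + 1):
        for b in range(m - a + 1):
            for c in range(m - a - b + 1):
                yield (a, b, c, m - a - b - c)


def equal_allele_freq_probability(m: int) -> Fraction:
    """Probability the sample's A1 and A2 allele counts are both m.

    Primary route: exact enumeration over all genotype count vectors of
    the multinomial masses whose A1 allele count equals m (the sample
    preserves the line's 1:1 allele ratio).
    """
    if m < 1:
        raise ValueError(f"sample size m must be >= 1, got {m}")
    ga4 = selfed_line_array()
    total = Fraction(0)
    for counts in _iter_count_vectors(m):
        if 2 * counts[0] + counts[1] + counts[2] == m:
            total += multinomial_mass(counts, ga4)
    return total


def equal_allele_freq_closed_form(m: int) -> Fraction:
    """Same probability via independent genes: C(2m, m) / 4^m.

    The 2m sampled gene copies are i.i.d. fair draws of A1 vs A2, so
    equal counts is a central binomial event.  Kept separate from the
    enumeration as a cross-check identity.
    """
    if m < 1:
        raise ValueError(f"sample size m must be >= 1, got {m}")
    return Fraction(comb(2 * m, m), 4**m)


def progeny_ic_from_sample(sc: SampleCounts, F=None):
    """IC of the progeny produced by random mating of a sample.

    With sample allele frequencies p and q = 1 - p, the progeny array
    is p^2 / pq / qp / q^2 and its IC is ``(p^2 + q^2) + 2pq F``.  A
    monomorphic sample gives (a, b) = (1, 0): fixation drives the
    coefficient to its maximum regardless of F.

    Returns the :class:`ProgenyIC` form, or the evaluated rational when
    ``F`` is given.
    """
    p = sc.p_a1
    q = 1 - p
    result = ProgenyIC(a=p * p + q * q, b=2 * p * q, p=p, q=q)
    if F is None:
        return result
    return result(_check_f(F))
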
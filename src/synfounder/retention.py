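"""Exact genotype-retention probabilities under multinomial sampling.

A sample of m plants is drawn with replacement from a genotypic array
(the 4-class GA4 or the collapsed 3-class GA3).  The probability that
every genotype class is represented at least once is computed the way
the reference tables lay it out: enumerate the *frequency sets*
(partitions of m into exactly `arity` positive parts), expand each set
into its distinct permutations (ordered assignments of counts to
labelled genotypes), and sum the exact multinomial masses.

An inclusion-exclusion closed form over genotype subsets serves as an
independent route to the same rational number and is asserted equal in
the test suite.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction
from math import comb, factorial
from typing import Iterator, Sequence

from .genetic_model import GenotypicArray

__all__ = [
    "FrequencySet",
    "PermutationRecord",
    "SetRow",
    "InclusionBreakdown",
    "enumerate_frequency_sets",
    "ndp",
    "multinomial_mass",
    "inclusion_probability",
    "inclusion_breakdown",
    "set_joint_probability",
    "inclusion_closed_form",
]


@dataclass(frozen=True)
class FrequencySet:
    """Unordered multiset of positive genotype counts summing to m.

    Stored canonically in nondecreasing order.
    """

    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.counts):
            raise ValueError("all counts in a frequency set must be >= 1")
        if tuple(sorted(self.counts)) != self.counts:
            raise ValueError("counts must be stored in nondecreasing order")

    @property
    def m(self) -> int:
        return sum(self.counts)

    @property
    def arity(self) -> int:
        return len(self.counts)

    def permutations(self) -> list[tuple[int, ...]]:
        """All distinct ordered assignments of the counts, sorted."""
        return sorted(set(itertools.permutations(self.counts)))


@dataclass(frozen=True)
class PermutationRecord:
    """One ordered assignment of a frequency set with its exact mass."""

    ordered_counts: tuple[int, ...]
    probability: Fraction


@dataclass(frozen=True)
class SetRow:
    """One frequency set with its permutation expansion and subtotal."""

    freq_set: FrequencySet
    ndp: int
    permutations: tuple[PermutationRecord, ...]
    set_total: Fraction


@dataclass(frozen=True)
class InclusionBreakdown:
    """Full per-set, per-permutation decomposition of the inclusion event."""

    m: int
    arity: int
    rows: tuple[SetRow, ...]
    grand_total: Fraction


def _partitions(n: int, k: int, minimum: int = 1) -> Iterator[tuple[int, ...]]:
    """Partitions of n into exactly k parts, each >= minimum, nondecreasing."""
    if k == 1:
        if n >= minimum:
            yield (n,)
        return
    for first in range(minimum, n // k + 1):
        for rest in _partitions(n - first, k - 1, first):
            yield (first, *rest)


def enumerate_frequency_sets(m: int, arity: int) -> list[FrequencySet]:
    """All partitions of m into exactly ``arity`` positive parts.

    These are the frequency sets whose permutations exhaust the ways a
    size-m sample can contain every genotype class at least once.
    """
    if arity not in (3, 4):
        raise ValueError(f"arity must be 3 or 4, got {arity}")
    if m < arity:
        raise ValueError(
            f"m={m} cannot include all {arity} genotypes; no frequency sets exist"
        )
    return [FrequencySet(p) for p in _partitions(m, arity)]


def ndp(fs: FrequencySet) -> int:
    """Number of distinct permutations of a frequency set.

    ``arity!`` divided by the factorials of the multiplicities of
    repeated counts (e.g. {1,1,4} -> 3, {2,2,2} -> 1).
    """
    result = factorial(fs.arity)
    for count in set(fs.counts):
        result //= factorial(fs.counts.count(count))
    return result


def multinomial_mass(ordered_counts: Sequence[int], ga: GenotypicArray) -> Fraction:
    """Exact multinomial probability of one ordered count vector.

    ``m! * prod(p_q^f_q) / prod(f_q!)`` with the array's class
    probabilities; zero counts are allowed (mass of the whole sample
    falling in the remaining classes).
    """
    if len(ordered_counts) != ga.arity:
        raise ValueError(
            f"counts length {len(ordered_counts)} != array arity {ga.arity}"
        )
    if any(c < 0 for c in ordered_counts):
        raise ValueError("counts must be nonnegative")
    m = sum(ordered_counts)
    mass = Fraction(factorial(m))
    for f_q, p_q in zip(ordered_counts, ga.probabilities):
        mass *= p_q**f_q
        mass /= factorial(f_q)
    return mass


def set_joint_probability(m: int, fs: FrequencySet, ga: GenotypicArray) -> Fraction:
    """Joint mass of all distinct permutations of one frequency set.

    For equiprobable classes (GA4) every permutation has the same mass,
    so this is ndp x one mass; for GA3 the permutations split by the
    heterozygote's count and are summed individually.
    """
    if fs.m != m:
        raise ValueError(f"frequency set sums to {fs.m}, expected m={m}")
    if fs.arity != ga.arity:
        raise ValueError("frequency set arity does not match the array")
    if len(set(ga.probabilities)) == 1:
        return ndp(fs) * multinomial_mass(fs.counts, ga)
    return sum(
        (multinomial_mass(perm, ga) for perm in fs.permutations()), Fraction(0)
    )


def inclusion_probability(m: int, ga: GenotypicArray) -> Fraction:
    """Probability a size-m sample contains every genotype class.

    Exact sum over frequency sets of their joint permutation masses.
    Returns 0 when ``m < arity`` (inclusion impossible).
    """
    if m < 1:
        raise ValueError(f"sample size m must be >= 1, got {m}")
    if m < ga.arity:
        return Fraction(0)
    return sum(
        (set_joint_probability(m, fs, ga) for fs in enumerate_frequency_sets(m, ga.arity)),
        Fraction(0),
    )


def inclusion_breakdown(m: int, ga: GenotypicArray) -> InclusionBreakdown:
    """Per-set, per-permutation decomposition of the inclusion probability.

    Mirrors the layout of the published worked tables: one row per
    frequency set with its distinct-permutation count, the mass of each
    permutation, the set subtotal, and the grand total.
    """
    if m < ga.arity:
        raise ValueError(
            f"m={m} cannot include all {ga.arity} genotypes; no breakdown exists"
        )
    rows = []
    total = Fraction(0)
    for fs in enumerate_frequency_sets(m, ga.arity):
        records = tuple(
            PermutationRecord(perm, multinomial_mass(perm, ga))
            for perm in fs.permutations()
        )
        subtotal = sum((r.probability for r in records), Fraction(0))
        rows.append(SetRow(fs, ndp(fs), records, subtotal))
        total += subtotal
    return InclusionBreakdown(m=m, arity=ga.arity, rows=tuple(rows), grand_total=total)


def inclusion_closed_form(m: int, ga: GenotypicArray) -> Fraction:
    """Inclusion probability by inclusion-exclusion over genotype subsets.

    sum over subsets S of classes of (-1)^|S| (1 - sum_{q in S} p_q)^m.
    Independent of the partition enumeration; used as its cross-check.
    """
    if m < 1:
        raise ValueError(f"sample size m must be >= 1, got {m}")
    total = Fraction(0)
    classes = range(ga.arity)
    for r in range(ga.arity + 1):
        for subset in itertools.combinations(classes, r):
            remaining = 1 - sum((ga.probabilities[q] for q in subset), Fraction(0))
            total += (-1) ** r * remaining**m
    return total


def n_compositions(m: int, arity: int) -> int:
    """Number of ordered count vectors with all parts >= 1: C(m-1, arity-1)."""
    return comb(m - 1, arity - 1)
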
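import itertools
from decimal import Decimal
from fractions import Fraction

import pytest
from hypothesis import given
from hypothesis import strategies as st

from synfounder._rounding import round_half_away, truncate
from synfounder.retention import (
    FrequencySet,
    enumerate_frequency_sets,
    inclusion_breakdown,
    inclusion_closed_form,
    inclusion_probability,
    multinomial_mass,
    n_compositions,
    ndp,
    set_joint_probability,
)


def brute_force_inclusion(m, ga) -> Fraction:
    """P(all classes present) by summing over every ordered sample."""
    total = Fraction(0)
    for sample in itertools.product(range(ga.arity), repeat=m):
        if set(sample) == set(range(ga.arity)):
            prob = Fraction(1)
            for cls in sample:
                prob *= ga.probabilities[cls]
            total += prob
    return total


class TestFrequencySets:
    def test_size_six_three_classes(self):
        sets = enumerate_frequency_sets(6, 3)
        assert [fs.counts for fs in sets] == [(1, 1, 4), (1, 2, 3), (2, 2, 2)]

    def test_counts_for_reference_sizes(self):
        assert len(enumerate_frequency_sets(15, 3)) == 19
        twelve = enumerate_frequency_sets(12, 3)
        assert len(twelve) == 12
        # seven sets of three distinct counts, four with a repeat, one uniform
        distinct = [fs for fs in twelve if len(set(fs.counts)) == 3]
        assert len(distinct) == 7
        assert FrequencySet((4, 4, 4)) in twelve

    def test_impossible_inclusion_raises(self):
        with pytest.raises(ValueError):
            enumerate_frequency_sets(2, 3)

    @given(m=st.integers(min_value=4, max_value=40), arity=st.sampled_from([3, 4]))
    def test_permutation_counts_exhaust_compositions(self, m, arity):
        sets = enumerate_frequency_sets(m, arity)
        assert sum(ndp(fs) for fs in sets) == n_compositions(m, arity)
        # every set enumerates exactly ndp distinct permutations
        for fs in sets:
            assert len(fs.permutations()) == ndp(fs)

    @pytest.mark.parametrize(
        "counts, expected",
        [((1, 2, 3), 6), ((1, 1, 4), 3), ((2, 2, 2), 1), ((3, 4, 4, 4), 4), ((3, 3, 4, 5), 12)],
    )
    def test_distinct_permutation_counts(self, counts, expected):
        assert ndp(FrequencySet(counts)) == expected


class TestMultinomialMass:
    def test_uniform_three_class_mass(self, ga3):
        assert multinomial_mass((2, 2, 2), ga3) == Fraction(90, 1024)

    def test_extreme_four_class_mass_is_tiny(self, ga4):
        mass = multinomial_mass((1, 1, 12, 1), ga4)
        assert round_half_away(mass, 7) == Decimal("0.0000025")

    def test_single_class_mass(self, ga3):
        assert multinomial_mass((6, 0, 0), ga3) == Fraction(1, 4) ** 6

    @pytest.mark.parametrize("m", range(1, 16))
    def test_completeness_mass_sums_to_one(self, m, ga4, ga3):
        for ga in (ga3, ga4):
            vectors = (
                counts
                for counts in itertools.product(range(m + 1), repeat=ga.arity)
                if sum(counts) == m
            )
            assert sum(multinomial_mass(v, ga) for v in vectors) == 1

    def test_shape_mismatch_rejected(self, ga4):
        with pytest.raises(ValueError):
            multinomial_mass((1, 2, 3), ga4)


class TestInclusionProbability:
    def test_four_class_size_fifteen(self, ga4):
        assert round_half_away(inclusion_probability(15, ga4), 4) == Decimal("0.9467")

    def test_three_class_size_three_exact(self, ga3):
        assert inclusion_probability(3, ga3) == Fraction(3, 16)

    def test_small_samples(self, ga4):
        assert inclusion_probability(3, ga4) == 0
        assert inclusion_probability(4, ga4) == Fraction(3, 32)

    @pytest.mark.parametrize("m", range(3, 8))
    def test_matches_brute_force_sample_enumeration(self, m, ga4, ga3):
        for ga in (ga3, ga4):
            assert inclusion_probability(m, ga) == brute_force_inclusion(m, ga)

    @pytest.mark.parametrize("m", range(1, 31))
    def test_enumeration_equals_inclusion_exclusion(self, m, ga4, ga3):
        for ga in (ga3, ga4):
            assert inclusion_probability(m, ga) == inclusion_closed_form(m, ga)

    def test_collapsed_array_dominates_and_both_monotone(self, ga4, ga3):
        prev3, prev4 = Fraction(0), Fraction(0)
        for m in range(1, 31):
            p3, p4 = inclusion_probability(m, ga3), inclusion_probability(m, ga4)
            assert p3 >= p4
            assert p3 >= prev3 and p4 >= prev4
            prev3, prev4 = p3, p4


class TestBreakdown:
    def test_size_six_three_class_permutation_masses(self, ga3):
        bd = inclusion_breakdown(6, ga3)
        rows = {row.freq_set.counts: row for row in bd.rows}
        masses_123 = [
            str(round_half_away(rec.probability, 3))
            for rec in rows[(1, 2, 3)].permutations
        ]
        assert masses_123 == ["0.059", "0.117", "0.029", "0.117", "0.029", "0.059"]
        masses_114 = [
            str(round_half_away(rec.probability, 3))
            for rec in rows[(1, 1, 4)].permutations
        ]
        assert masses_114 == ["0.015", "0.117", "0.015"]
        assert str(round_half_away(rows[(2, 2, 2)].set_total, 3)) == "0.088"
        assert bd.grand_total == inclusion_probability(6, ga3)

    @pytest.mark.parametrize(
        "counts, decimals, expected",
        [
            ((4, 5, 6), 4, "0.1316"),
            ((1, 1, 13), 4, "0.0016"),
        ],
    )
    def test_size_fifteen_three_class_set_totals(self, ga3, counts, decimals, expected):
        joint = set_joint_probability(15, FrequencySet(counts), ga3)
        assert str(round_half_away(joint, decimals)) == expected

    def test_size_fifteen_uniform_set_total(self, ga3):
        # 15!/(5!5!5!) (1/4)^10 (1/2)^5 = 0.0225531..., first four
        # decimals 0.0225
        joint = set_joint_probability(15, FrequencySet((5, 5, 5)), ga3)
        assert joint == Fraction(756756, 2**25)
        assert str(truncate(joint, 4)) == "0.0225"

    def test_size_fifteen_four_class_set_contributions(self, ga4):
        near_uniform = set_joint_probability(15, FrequencySet((3, 4, 4, 4)), ga4)
        assert str(round_half_away(near_uniform, 4)) == "0.0587"
        spread = set_joint_probability(15, FrequencySet((3, 3, 4, 5)), ga4)
        assert spread == Fraction(4729725, 33554432)
        # printed to 6 d.p. this value truncates to 0.140956
        assert str(truncate(spread, 6)) == "0.140956"
        assert str(round_half_away(spread, 6)) == "0.140957"

    def test_set_joint_probability_equals_permutation_sum(self, ga3):
        fs = FrequencySet((2, 6, 7))
        expected = sum(
            (multinomial_mass(p, ga3) for p in fs.permutations()), Fraction(0)
        )
        assert set_joint_probability(15, fs, ga3) == expected

    def test_breakdown_totals_and_bookkeeping(self, ga3, ga4):
        for ga, m in [(ga3, 15), (ga4, 10)]:
            bd = inclusion_breakdown(m, ga)
            assert bd.grand_total == sum(
                (row.set_total for row in bd.rows), Fraction(0)
            )
            assert sum(row.ndp for row in bd.rows) == n_compositions(m, ga.arity)

    def test_breakdown_rejects_impossible_inclusion(self, ga4):
        with pytest.raises(ValueError):
            inclusion_breakdown(3, ga4)
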
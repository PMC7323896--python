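"""Allele frequencies, HW expectations, the conditional sample probability
and its enumeration, checked against exact rational arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hwtest import (
    MultiAlleleCounts,
    TwoAlleleCounts,
    allele_frequencies,
    chi_square_test,
    conditional_log_prob,
    enumerate_two_allele_conditional,
    expected_hw_counts,
    fixation_index,
)

from _oracles import exact_conditional_prob
from conftest import random_valid_two_allele


class TestAlleleFrequencies:
    def test_worked_sample(self, worked):
        f = allele_frequencies(worked)
        assert f[0] == pytest.approx(0.7, abs=1e-15)
        assert f.q == pytest.approx(0.3, abs=1e-15)

    def test_all_heterozygotes(self):
        f = allele_frequencies(TwoAlleleCounts(0, 40, 0))
        assert f[0] == f[1] == 0.5

    def test_three_equal_homozygote_classes(self):
        c = MultiAlleleCounts.from_class_counts("ABC", [7, 0, 7, 0, 0, 7])
        np.testing.assert_allclose(allele_frequencies(c).p, 1 / 3)

    @given(st.lists(st.integers(0, 100), min_size=3, max_size=3))
    @settings(derandomize=True, max_examples=100)
    def test_frequencies_sum_to_one(self, cells):
        if sum(cells) == 0:
            return
        c = TwoAlleleCounts(*cells)
        assert abs(allele_frequencies(c).p.sum() - 1.0) < 1e-12


class TestExpectedCounts:
    def test_worked_sample(self, worked):
        e = expected_hw_counts(worked)
        np.testing.assert_allclose(
            [e[0, 0], e[1, 0], e[1, 1]], [98.0, 84.0, 18.0], atol=1e-9
        )

    def test_fixed_point_at_perfect_hw(self, hw_perfect):
        e = expected_hw_counts(hw_perfect)
        np.testing.assert_allclose(
            [e[0, 0], e[1, 0], e[1, 1]], [98.0, 84.0, 18.0], atol=1e-9
        )

    def test_monomorphic(self):
        e = expected_hw_counts(TwoAlleleCounts(30, 0, 0))
        np.testing.assert_allclose([e[0, 0], e[1, 0], e[1, 1]], [30.0, 0.0, 0.0])

    def test_expected_counts_sum_to_n(self, four_allele):
        assert expected_hw_counts(four_allele).sum() == pytest.approx(
            four_allele.N, abs=1e-9
        )


class TestConditionalLogProb:
    def test_single_heterozygote_is_certain(self):
        assert conditional_log_prob(TwoAlleleCounts(0, 1, 0)) == pytest.approx(0.0, abs=1e-12)

    def test_two_individual_enumeration(self):
        # with nA = na = 2 the only tables are (1,0,1) and (0,2,0)
        p_hom = np.exp(conditional_log_prob(TwoAlleleCounts(1, 0, 1)))
        p_het = np.exp(conditional_log_prob(TwoAlleleCounts(0, 2, 0)))
        assert p_hom == pytest.approx(1 / 3, rel=1e-12)
        assert p_het == pytest.approx(2 / 3, rel=1e-12)

    @pytest.mark.parametrize(
        "table", [(119, 42, 39), (0, 1, 0), (5, 0, 5), (1000, 3000, 6000)]
    )
    def test_matches_exact_rational_oracle(self, table):
        import math

        expected = exact_conditional_prob(*table)
        got = conditional_log_prob(TwoAlleleCounts(*table))
        # big-int-safe log of the exact rational value
        ln_exact = math.log(expected.numerator) - math.log(expected.denominator)
        assert got == pytest.approx(ln_exact, rel=1e-9, abs=1e-9)

    def test_multiallelic_generalization(self, four_allele):
        # cross-check the k-allele formula against a direct rational computation
        import math
        from math import factorial

        m = four_allele
        n = (m.table + m.table.T).sum(axis=1)
        num = factorial(m.N) * 2**m.het_total
        for x in n:
            num *= factorial(int(x))
        den = factorial(2 * m.N)
        for x in m.class_counts:
            den *= factorial(int(x))
        ln_exact = math.log(num) - math.log(den)
        assert conditional_log_prob(m) == pytest.approx(ln_exact, rel=1e-9)


class TestEnumeration:
    def test_minimal_cases(self):
        d = enumerate_two_allele_conditional(2, 2)
        assert d.support.tolist() == [0, 2]
        np.testing.assert_allclose(d.probs, [1 / 3, 2 / 3], rtol=1e-12)
        d = enumerate_two_allele_conditional(1, 1)
        assert d.support.tolist() == [1]
        np.testing.assert_allclose(d.probs, [1.0])

    def test_worked_sample_support(self):
        d = enumerate_two_allele_conditional(280, 120)
        assert len(d.support) == 61
        assert d.support[0] == 0 and d.support[-1] == 120
        assert np.all(np.diff(d.support) == 2)
        assert d.probs.sum() == pytest.approx(1.0, abs=1e-10)

    def test_odd_total_rejected(self):
        with pytest.raises(ValueError, match="even"):
            enumerate_two_allele_conditional(3, 2)

    @given(st.integers(0, 30), st.integers(0, 30))
    @settings(derandomize=True, max_examples=200)
    def test_normalization_and_parity(self, nA, na):
        if (nA + na) % 2 or nA + na < 2:
            return
        d = enumerate_two_allele_conditional(nA, na)
        assert d.probs.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(d.support % 2 == nA % 2)
        assert np.all(d.support <= min(nA, na))


class TestFixationIndex:
    def test_worked_sample(self, worked):
        assert fixation_index(worked) == pytest.approx(0.5, abs=1e-12)

    def test_zero_at_perfect_hw(self, hw_perfect):
        assert fixation_index(hw_perfect) == pytest.approx(0.0, abs=1e-12)

    def test_all_heterozygotes(self):
        assert fixation_index(TwoAlleleCounts(0, 60, 0)) == pytest.approx(-1.0)

    def test_undefined_when_monomorphic(self):
        with pytest.raises(ValueError):
            fixation_index(TwoAlleleCounts(50, 0, 0))

    def test_chi_square_equals_n_f_squared(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            c = random_valid_two_allele(rng)
            stat = chi_square_test(c).statistic
            assert stat == pytest.approx(c.N * fixation_index(c) ** 2, rel=1e-9, abs=1e-9)
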
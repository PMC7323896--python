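"""Chi-squared, G, Hogben/Levene and Cannings & Edwards tests."""

import numpy as np
import pytest

from hwtest import (
    TwoAlleleCounts,
    cannings_edwards_test,
    chi_square_test,
    expected_hw_counts,
    fixation_index,
    g_test,
    levene_hogben_test,
)
from hwtest.counts import allele_counts

from conftest import random_valid_two_allele


class TestChiSquare:
    def test_worked_sample_uncorrected(self, worked):
        r = chi_square_test(worked)
        assert r.statistic == pytest.approx(50.0, abs=1e-9)
        assert r.df == 1
        assert not r.correction
        # chi2 = 50 at 1 df is far beyond any conventional threshold
        assert r.p_value < 1e-10
        assert any("genotyping" in n for n in r.notes)

    def test_worked_sample_corrected(self, worked):
        r = chi_square_test(worked, correction=True)
        # (20.5^2/98 + 41.5^2/84 + 20.5^2/18)
        assert r.statistic == pytest.approx(
            20.5**2 / 98 + 41.5**2 / 84 + 20.5**2 / 18, rel=1e-12
        )
        assert r.correction

    def test_perfect_hw_is_null(self, hw_perfect):
        r = chi_square_test(hw_perfect)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_k4_degrees_of_freedom(self, four_allele):
        r = chi_square_test(four_allele)
        assert r.df == 6
        assert 0.0 <= r.p_value <= 1.0

    def test_correction_restricted_to_two_alleles(self, four_allele):
        with pytest.raises(ValueError, match="two alleles"):
            chi_square_test(four_allele, correction=True)

    def test_sum_of_squares_identity(self, four_allele):
        # chi2 = sum(o^2/e) - N, the computational form for k alleles
        e = expected_hw_counts(four_allele)
        e = np.array([e[i, j] for i, j in four_allele.genotype_classes])
        o = four_allele.class_counts
        alt = float(np.sum(o**2 / e) - four_allele.N)
        assert chi_square_test(four_allele).statistic == pytest.approx(alt, rel=1e-12)

    def test_equals_n_f_squared(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            c = random_valid_two_allele(rng)
            assert chi_square_test(c).statistic == pytest.approx(
                c.N * fixation_index(c) ** 2, rel=1e-9, abs=1e-9
            )


class TestGTest:
    def test_perfect_hw(self, hw_perfect):
        r = g_test(hw_perfect)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_direct_formula_oracle(self, worked):
        o = np.array([119.0, 42.0, 39.0])
        e = np.array([98.0, 84.0, 18.0])
        expected = 2.0 * np.sum(o * np.log(o / e))
        assert g_test(worked).statistic == pytest.approx(expected, rel=1e-9)

    def test_correction_never_increases_g(self):
        rng = np.random.default_rng(17)
        for _ in range(300):
            c = random_valid_two_allele(rng)
            g0 = g_test(c).statistic
            g1 = g_test(c, correction=True).statistic
            assert g1 <= g0 + 1e-12
            assert g1 >= 0.0


class TestLeveneHogben:
    def test_worked_sample_conditional_expectation(self, worked):
        # E[H] = 280 * 120 / 399
        r = levene_hogben_test(worked)
        assert r.df == 1
        e_h = 280 * 120 / 399
        assert e_h == pytest.approx(84.21052631578948)
        o = np.array([119.0, 42.0, 39.0])
        e = np.array([280 * 279 / (2 * 399), e_h, 120 * 119 / (2 * 399)])
        assert r.statistic == pytest.approx(float(np.sum((o - e) ** 2 / e)), rel=1e-12)

    def test_conditional_expectations_sum_to_n(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            c = random_valid_two_allele(rng)
            nA, na = (int(x) for x in allele_counts(c).n)
            N = c.N
            total = (nA * (nA - 1) + na * (na - 1)) / (2 * (2 * N - 1)) + nA * na / (
                2 * N - 1
            )
            assert total == pytest.approx(N, rel=1e-12)

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError):
            levene_hogben_test(TwoAlleleCounts(50, 0, 0))


class TestCanningsEdwards:
    def test_perfect_hw(self, hw_perfect):
        r = cannings_edwards_test(hw_perfect)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_direct_formula_oracle(self, worked):
        # deviations |o-e| = (21, 42, 21) reduced by (0.5, 1, 0.5)
        expected = 20.5**2 / 98 + 41.0**2 / 84 + 20.5**2 / 18
        assert cannings_edwards_test(worked).statistic == pytest.approx(
            expected, rel=1e-9
        )

    def test_never_exceeds_uncorrected_chi2(self):
        rng = np.random.default_rng(29)
        for _ in range(300):
            c = random_valid_two_allele(rng)
            assert (
                cannings_edwards_test(c).statistic
                <= chi_square_test(c).statistic + 1e-12
            )


class TestPValueContract:
    def test_p_monotone_in_statistic(self):
        rng = np.random.default_rng(31)
        results = [chi_square_test(random_valid_two_allele(rng)) for _ in range(50)]
        results.sort(key=lambda r: r.statistic)
        ps = [r.p_value for r in results]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))
        assert all(0.0 <= p <= 1.0 for p in ps)
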
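"""Welch t, Cyber-t and Bayesian t per-gene tests."""

import numpy as np
import pytest
from scipy import stats

from predex import (
    DegenerateDataError,
    bayes_t_matrix,
    bayes_t_test,
    cyber_t_matrix,
    cyber_t_test,
    welch_t_matrix,
    welch_t_test,
)

CTRL = np.array([0.0, 2.0])
TRT = np.array([1.0, 3.0])


class TestWelch:
    def test_hand_evaluated_example(self):
        r = welch_t_test(CTRL, TRT)
        assert r.statistic == pytest.approx(1 / np.sqrt(2))
        assert r.df == pytest.approx(2.0)

    def test_identical_samples_give_zero_statistic(self):
        r = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(1.0)
        assert not r.called

    def test_agrees_with_scipy_unequal_variance_ttest(self, rng):
        c = rng.normal(0, 1, (50, 4))
        t = rng.normal(0.5, 2, (50, 6))
        stat, df, p = welch_t_matrix(c, t)
        ref = stats.ttest_ind(t, c, axis=1, equal_var=False)
        np.testing.assert_allclose(stat, ref.statistic, rtol=1e-10)
        np.testing.assert_allclose(p, ref.pvalue, rtol=1e-9)

    def test_null_rejection_rate_close_to_alpha(self, rng):
        c = rng.normal(0, 1, (10_000, 4))
        t = rng.normal(0, 1, (10_000, 4))
        _, _, p = welch_t_matrix(c, t)
        rate = np.mean(p < 0.05)
        assert 0.03 < rate < 0.055  # slightly conservative at n=4

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            welch_t_test([1.0, 1.0], [2.0, 2.0])


class TestCyberT:
    def test_degrees_of_freedom_rule_at_n4(self):
        # n_g = 8 -> nu0 = 2 pseudo-observations, df = 2 + 8 - 2 = 8
        r = cyber_t_test([0.0, 2.0, 1.0, 3.0], [1.0, 3.0, 2.0, 4.0])
        assert r.df == pytest.approx(8.0)

    def test_identical_samples_give_zero_statistic(self):
        r = cyber_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(1.0)

    def test_matches_scalar_formula_oracle(self, rng):
        c = rng.normal(0, 1, 4)
        t = rng.normal(1, 2, 4)
        r = cyber_t_test(c, t)
        # term-by-term scalar evaluation
        nc = nt = 4
        ng = 8
        nu0 = 10 - ng
        pooled = list(c) + list(t)
        mbar = sum(pooled) / ng
        s2g = sum((v - mbar) ** 2 for v in pooled) / (ng - 1)
        sigma0 = ((ng - 1) / ng) * s2g
        sc2 = np.var(c, ddof=1)
        st2 = np.var(t, ddof=1)
        vc = (nu0 * sigma0 + (nc - 1) * sc2) / (nu0 + nc - 2)
        vt = (nu0 * sigma0 + (nt - 1) * st2) / (nu0 + nt - 2)
        expected = (np.mean(t) - np.mean(c)) / np.sqrt(vt / nt + vc / nc)
        assert r.statistic == pytest.approx(expected, rel=1e-12)

    def test_nu0_floors_at_zero_for_large_samples(self, rng):
        c = rng.normal(0, 1, (5, 8))
        t = rng.normal(0, 1, (5, 8))
        _, df, _ = cyber_t_matrix(c, t)
        assert np.all(df == 14.0)  # nu0 = max(10-16, 0) = 0


class TestBayesT:
    def test_pseudo_observation_counts_at_n4(self):
        # nu0 = n_g = 8, nu_n = 8 + 8 - 2 = 14
        r = bayes_t_test([0.0, 2.0, 1.0, 3.0], [1.0, 3.0, 2.0, 4.0])
        assert r.df == pytest.approx(14.0)

    def test_zero_mean_difference_gives_p_one(self):
        r = bayes_t_test([0.0, 1.0, 2.0], [2.0, 1.0, 0.0])
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_matches_scalar_formula_oracle(self, rng):
        c = rng.normal(0, 1, 4)
        t = rng.normal(1, 2, 4)
        r = bayes_t_test(c, t)
        nc = nt = 4
        ng = nu0 = 8
        pooled = list(c) + list(t)
        mbar = sum(pooled) / ng
        sigma0 = sum((v - mbar) ** 2 for v in pooled) / (ng - 1)
        nu_n = nu0 + nc + nt - 2
        sn2 = (nu0 * sigma0 + (nc - 1) * np.var(c, ddof=1) + (nt - 1) * np.var(t, ddof=1)) / nu_n
        expected = (np.mean(t) - np.mean(c)) / np.sqrt(sn2 * (1 / nt + 1 / nc))
        assert r.statistic == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("matrix_fn", [welch_t_matrix, cyber_t_matrix, bayes_t_matrix])
class TestSharedProperties:
    def test_location_invariance(self, matrix_fn, rng):
        c = rng.normal(0, 1, (20, 4))
        t = rng.normal(1, 2, (20, 4))
        s0, d0, p0 = matrix_fn(c, t)
        s1, d1, p1 = matrix_fn(c + 7.3, t + 7.3)
        np.testing.assert_allclose(s0, s1, rtol=1e-9)
        np.testing.assert_allclose(p0, p1, rtol=1e-8)

    def test_label_swap_negates_statistic(self, matrix_fn, rng):
        c = rng.normal(0, 1, (20, 4))
        t = rng.normal(1, 2, (20, 4))
        s0, _, p0 = matrix_fn(c, t)
        s1, _, p1 = matrix_fn(t, c)
        np.testing.assert_allclose(s1, -s0, rtol=1e-10)
        np.testing.assert_allclose(p1, p0, rtol=1e-10)
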
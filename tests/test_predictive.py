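"""Normal-inverse-gamma posterior, predictive variance and interval."""

import math

import numpy as np
import pytest

from predex import (
    DegenerateDataError,
    InsufficientDataError,
    NIGHyperparams,
    PredictiveParams,
    ValidationError,
    credibility_interval,
    default_beta,
    posterior_update,
    predictive_variance,
)
from helpers_oracle import t_upper_quantile_oracle


class TestDefaultBeta:
    @pytest.mark.parametrize(
        "y, tau, expected",
        [([0.0, 1.0], 3.0, 1.0), ([-2.0, 0.0, 2.0], 3.0, 16.0)],
    )
    def test_hand_values(self, y, tau, expected):
        assert default_beta(y, tau) == pytest.approx(expected)

    def test_matches_independent_range_scan(self, rng):
        y = rng.standard_normal(1000)
        lo = hi = y[0]
        for v in y:  # independent scalar scan
            lo, hi = min(lo, v), max(hi, v)
        assert default_beta(y, 3.0) == pytest.approx((hi - lo) ** 2)

    def test_zero_range_rejected(self):
        with pytest.raises(DegenerateDataError):
            default_beta([1.0, 1.0, 1.0], 3.0)


class TestPosteriorUpdate:
    PRIOR = NIGHyperparams(mu0=0.0, lam=0.01, tau=3.0, beta=1.0)

    def test_constant_sample_closed_form(self):
        post = posterior_update([1.0, 1.0, 1.0, 1.0], self.PRIOR)
        assert post.mu_star == pytest.approx(4 / 4.01)
        assert post.tau_star == 8.0
        assert post.beta_star == pytest.approx(1 + 0 + (4 * 0.01 / 4.01) * 1.0)

    def test_lambda_to_zero_limit(self, rng):
        y = rng.standard_normal(20)
        tiny = NIGHyperparams(mu0=5.0, lam=1e-12, tau=3.0, beta=2.0)
        post = posterior_update(y, tiny)
        assert post.mu_star == pytest.approx(y.mean(), rel=1e-9)
        assert post.beta_star == pytest.approx(2.0 + 19 * y.var(ddof=1), rel=1e-9)

    def test_matches_term_by_term_formula_oracle(self, rng):
        y = rng.standard_normal(50)
        prior = NIGHyperparams(mu0=0.3, lam=0.5, tau=4.0, beta=2.5)
        post = posterior_update(y, prior)
        # independent scalar evaluation of the update
        n = len(y)
        ybar = sum(float(v) for v in y) / n
        s2 = sum((float(v) - ybar) ** 2 for v in y) / (n - 1)
        mu = (n / (n + 0.5)) * ybar + (0.5 / (n + 0.5)) * 0.3
        beta_s = 2.5 + (n - 1) * s2 + n * 0.5 * (ybar - 0.3) ** 2 / (n + 0.5)
        assert post.mu_star == pytest.approx(mu, rel=1e-12)
        assert post.beta_star == pytest.approx(beta_s, rel=1e-12)
        assert post.tau_star == 4.0 + n + 1

    def test_standard_rule_gives_textbook_dof(self, rng):
        y = rng.standard_normal(10)
        post = posterior_update(y, self.PRIOR, tau_star_rule="standard")
        assert post.tau_star == 3.0 + 10

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            posterior_update([1.0], self.PRIOR)

    def test_beta_star_decomposition_nonnegative(self, rng):
        for _ in range(25):
            y = rng.standard_normal(rng.integers(2, 40))
            prior = NIGHyperparams(mu0=float(rng.normal()), lam=0.2, tau=3.5, beta=1.0)
            post = posterior_update(y, prior)
            n, ybar, s2 = len(y), y.mean(), y.var(ddof=1) if len(y) > 1 else 0.0
            a = (n - 1) * s2
            b = n * 0.2 * (ybar - prior.mu0) ** 2 / (n + 0.2)
            assert a >= 0 and b >= 0
            assert post.beta_star - 1.0 == pytest.approx(a + b, rel=1e-9, abs=1e-12)

    def test_location_equivariance(self, rng):
        y = rng.standard_normal(30)
        c = 2.25
        p0 = NIGHyperparams(mu0=0.4, lam=0.3, tau=3.0, beta=1.7)
        p1 = NIGHyperparams(mu0=0.4 + c, lam=0.3, tau=3.0, beta=1.7)
        a = posterior_update(y, p0)
        b = posterior_update(y + c, p1)
        assert b.mu_star == pytest.approx(a.mu_star + c, rel=1e-12)
        assert b.beta_star == pytest.approx(a.beta_star, rel=1e-12)
        assert b.tau_star == a.tau_star
        assert predictive_variance(b) == pytest.approx(predictive_variance(a), rel=1e-12)


class TestPredictiveVariance:
    def test_plug_in_value(self):
        post = PredictiveParams(mu_star=0.0, tau_star=4.0, beta_star=1.0, n_ref=1, lam=1.0)
        assert predictive_variance(post) == pytest.approx(0.75)

    def test_linear_in_beta_star(self):
        a = PredictiveParams(0.0, 6.0, 2.0, 5, 0.5)
        b = PredictiveParams(0.0, 6.0, 4.0, 5, 0.5)
        assert predictive_variance(b) == pytest.approx(2 * predictive_variance(a))

    def test_matches_term_by_term_oracle_from_update(self, rng):
        y = rng.standard_normal(50)
        prior = NIGHyperparams(mu0=0.3, lam=0.5, tau=4.0, beta=2.5)
        post = posterior_update(y, prior)
        n, lam, ts, bs = post.n_ref, post.lam, post.tau_star, post.beta_star
        expected = (ts / (ts - 2.0)) * (bs * (n + lam + 1.0) / (ts * (n + lam)))
        assert predictive_variance(post) == pytest.approx(expected, rel=1e-12)

    def test_undefined_below_two_dof(self):
        with pytest.raises(DegenerateDataError):
            predictive_variance(PredictiveParams(0.0, 2.0, 1.0, 1, 1.0))


class TestCredibilityInterval:
    POST = PredictiveParams(mu_star=1.5, tau_star=8.0, beta_star=3.0, n_ref=4, lam=0.01)

    def test_symmetry_about_location(self):
        lo, hi = credibility_interval(self.POST, 0.05)
        assert hi - self.POST.mu_star == pytest.approx(self.POST.mu_star - lo)

    def test_collapses_as_alpha_to_one(self):
        lo, hi = credibility_interval(self.POST, 1 - 1e-12)
        assert hi - lo == pytest.approx(0.0, abs=1e-6)

    def test_half_width_matches_quadrature_bisection_quantile(self):
        # tau*=8, location 0, unit predictive variance by construction:
        # pick beta* so that Var = 1.
        n, lam, ts = 4, 0.01, 8.0
        beta_star = (ts - 2.0) * (ts * (n + lam)) / (ts * (n + lam + 1.0))
        post = PredictiveParams(0.0, ts, beta_star, n, lam)
        assert predictive_variance(post) == pytest.approx(1.0)
        lo, hi = credibility_interval(post, 0.05)
        assert hi == pytest.approx(t_upper_quantile_oracle(0.975, 8.0), abs=1e-7)

    def test_invalid_alpha(self):
        with pytest.raises(ValidationError):
            credibility_interval(self.POST, 1.5)


class TestPredictiveCoverage:
    def test_95pct_interval_covers_heldout_point(self, rng):
        """With a weak prior, the 95% predictive interval built from 999
        normal draws contains the held-out 1000th draw ~95% of the time."""
        n_rep, covered = 2000, 0
        mu, sigma = -14.0, math.sqrt(0.8)
        for _ in range(n_rep):
            y = rng.normal(mu, sigma, 1000)
            ref, new = y[:999], y[999]
            prior = NIGHyperparams(mu0=0.0, lam=1e-2, tau=3.0).with_beta(
                default_beta(ref, 3.0)
            )
            lo, hi = credibility_interval(posterior_update(ref, prior), 0.05)
            covered += lo <= new <= hi
        assert covered / n_rep == pytest.approx(0.95, abs=0.02)
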
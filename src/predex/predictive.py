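"""Conjugate normal-inverse-gamma model for the treatment-effect population.

The observed mean treatment effects y_1, ..., y_n are modelled as an i.i.d.
normal sample with unknown mean mu and variance sigma^2 carrying the
conjugate prior

    mu | sigma^2 ~ N(mu0, sigma^2 / lambda),    sigma^2 ~ InvGamma(tau/2, beta/2).

The posterior is again normal-inverse-gamma, and the predictive distribution
of a new, unobserved effect Y_{n+1} is a location-scale Student t:

    Y_{n+1} | y ~ t_{tau*}( mu*,  beta* (n + lambda + 1) / (tau* (n + lambda)) ).

This module provides the hyperparameter containers, the posterior update,
the predictive variance and the equal-tailed predictive (credibility)
interval.  Note the degrees-of-freedom update used throughout is
``tau* = tau + n + 1``; the textbook conjugate update ``tau + n`` is
available via ``tau_star_rule="standard"`` for sensitivity analysis only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, InsufficientDataError, ValidationError

__all__ = [
    "NIGHyperparams",
    "PredictiveParams",
    "default_beta",
    "posterior_update",
    "predictive_variance",
    "credibility_interval",
]

TauStarRule = Literal["printed", "standard"]

#: Default weakly-informative hyperparameters (beta=None means: derive it
#: from the data range via :func:`default_beta`).
DEFAULT_MU0 = 0.0
DEFAULT_LAMBDA = 1e-2
DEFAULT_TAU = 3.0


@dataclass(frozen=True)
class NIGHyperparams:
    """Prior hyperparameters (mu0, lambda, tau, beta) of the NIG prior.

    ``beta=None`` marks the prior scale as data-derived: consumers fill it
    with ``default_beta(y, tau)`` computed once on the full effect vector.
    """

    mu0: float = DEFAULT_MU0
    lam: float = DEFAULT_LAMBDA
    tau: float = DEFAULT_TAU
    beta: float | None = None

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ValidationError(f"lambda must be positive, got {self.lam}")
        if not self.tau > 2:
            raise ValidationError(
                f"tau must exceed 2 (prior variance mean defined), got {self.tau}"
            )
        if self.beta is not None and not self.beta > 0:
            raise ValidationError(f"beta must be positive, got {self.beta}")

    def with_beta(self, beta: float) -> "NIGHyperparams":
        return NIGHyperparams(mu0=self.mu0, lam=self.lam, tau=self.tau, beta=beta)


@dataclass(frozen=True)
class PredictiveParams:
    """Posterior quantities feeding the Student-t predictive density.

    Attributes
    ----------
    mu_star : posterior (and predictive) location.
    tau_star : predictive degrees of freedom.
    beta_star : updated inverse-gamma scale.
    n_ref : size of the reference sample the posterior was computed from.
    lam : prior precision scaling, carried through for the variance formula.
    """

    mu_star: float
    tau_star: float
    beta_star: float
    n_ref: int
    lam: float


def _tau_star(tau: float, n: int, rule: TauStarRule) -> float:
    # "printed": tau + n + 1; "standard": the textbook conjugate tau + n.
    if rule == "printed":
        return tau + n + 1
    if rule == "standard":
        return tau + n
    raise ValidationError(f"unknown tau_star_rule: {rule!r}")


def default_beta(y, tau: float) -> float:
    """Data-driven prior scale beta = (tau - 2) * R^2, R = max(y) - min(y).

    Chosen so the prior mean of sigma^2 equals the squared range of the
    observed effects — a weakly informative choice on the data's own scale.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.size < 2:
        raise InsufficientDataError("default_beta needs at least 2 observations")
    if not tau > 2:
        raise ValidationError(f"tau must exceed 2, got {tau}")
    r = float(np.max(y) - np.min(y))
    if r == 0.0:
        raise DegenerateDataError("all effects equal: range is zero, prior scale undefined")
    return (tau - 2) * r * r


def posterior_update(
    y_ref,
    prior: NIGHyperparams,
    tau_star_rule: TauStarRule = "printed",
) -> PredictiveParams:
    """Update the NIG prior with the reference sample ``y_ref``.

    Returns the posterior/predictive parameters

        mu*   = (n/(n+lambda)) ybar + (lambda/(n+lambda)) mu0
        tau*  = tau + n + 1
        beta* = beta + (n-1) s^2 + n lambda (ybar - mu0)^2 / (n + lambda)

    with ybar, s^2 the sample mean and (n-1)-denominator variance of
    ``y_ref``.  ``prior.beta`` must be set (use :func:`default_beta`).
    """
    y = np.asarray(y_ref, dtype=float).ravel()
    n = y.size
    if n < 2:
        raise InsufficientDataError(f"posterior update needs >= 2 observations, got {n}")
    if prior.beta is None:
        raise ValidationError("prior.beta is unset; compute it with default_beta first")
    ybar = float(np.mean(y))
    s2 = float(np.var(y, ddof=1))
    lam = prior.lam
    mu_star = (n / (n + lam)) * ybar + (lam / (n + lam)) * prior.mu0
    beta_star = prior.beta + (n - 1) * s2 + n * lam * (ybar - prior.mu0) ** 2 / (n + lam)
    return PredictiveParams(
        mu_star=mu_star,
        tau_star=_tau_star(prior.tau, n, tau_star_rule),
        beta_star=beta_star,
        n_ref=n,
        lam=lam,
    )


def predictive_variance(post: PredictiveParams) -> float:
    """Variance of the Student-t predictive distribution of a new effect.

        Var(Y_{n+1} | y) = (tau*/(tau*-2)) * beta* (n + lambda + 1) / (tau* (n + lambda))

    Defined only for tau* > 2.
    """
    ts = post.tau_star
    if not ts > 2:
        raise DegenerateDataError(f"predictive variance undefined for tau* = {ts} <= 2")
    n, lam = post.n_ref, post.lam
    return (ts / (ts - 2)) * (post.beta_star * (n + lam + 1) / (ts * (n + lam)))


def credibility_interval(post: PredictiveParams, alpha: float) -> tuple[float, float]:
    """Equal-tailed 100(1-alpha)% predictive interval for a new effect.

    The interval is ``mu* -/+ t_{1-alpha/2, tau*} * sqrt(Var)`` with Var the
    predictive variance; it is symmetric about mu*.
    """
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must lie in (0, 1), got {alpha}")
    half = float(stats.t.ppf(1 - alpha / 2, post.tau_star)) * math.sqrt(
        predictive_variance(post)
    )
    return (post.mu_star - half, post.mu_star + half)
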
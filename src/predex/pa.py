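"""Sequential predictive-interval criterion for differential expression.

The detector orders the per-gene effects y increasingly and visits them one
by one.  At each step the remaining effects — everything except the gene
under test and every gene already called differential — form the reference
sample of the normal-inverse-gamma posterior; the call threshold is the
half-width of the predictive interval with its location forced to zero:

    call gene (g)  iff  |y_(g)| > t_{1-alpha/2, tau*} * sqrt(Var(Y_new | reference)).

A called gene leaves the reference pool for all later steps, so one clear
outlier cannot inflate the predictive spread used to judge the others.  The
prior scale beta is fixed once from the *full* effect vector via
``beta = (tau - 2) R^2`` and never shrinks with the pool: the prior must not
depend on which genes end up called.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats

from .dataset import TreatmentEffects
from .errors import InsufficientDataError, ValidationError
from .predictive import NIGHyperparams, TauStarRule, default_beta

__all__ = ["DetectionResult", "pa_detect"]

ProcessingOrder = Literal["increasing", "extremity"]


@dataclass(frozen=True)
class DetectionResult:
    """Per-gene calls of a detector, in the original gene order.

    ``threshold[g]`` is the interval half-width in force when gene g was
    tested; ``called[g]`` is true iff ``|y[g]| > threshold[g]``.  ``order``
    maps processing step -> original gene index.  ``mu_star`` carries the
    data-driven posterior location at each gene's step, reported for
    diagnostics only (the call itself always uses location zero).
    """

    gene_ids: list[str]
    y: np.ndarray = field(repr=False)
    called: np.ndarray = field(repr=False)
    threshold: np.ndarray = field(repr=False)
    order: np.ndarray = field(repr=False)
    method_name: str = "pa"
    mu_star: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_called(self) -> int:
        return int(np.count_nonzero(self.called))


class _TQuantileCache:
    """Memoised upper t quantiles keyed by degrees of freedom.

    The sequential pass needs one quantile per step but the degrees of
    freedom only take as many values as there are distinct pool sizes, so a
    dict cache removes nearly all ``t.ppf`` calls.
    """

    def __init__(self, q: float) -> None:
        self.q = q
        self._cache: dict[float, float] = {}

    def __call__(self, df: float) -> float:
        t = self._cache.get(df)
        if t is None:
            t = float(stats.t.ppf(self.q, df))
            self._cache[df] = t
        return t


def pa_detect(
    effects: TreatmentEffects,
    prior: NIGHyperparams | None = None,
    alpha: float = 0.05,
    *,
    order: ProcessingOrder = "increasing",
    tau_star_rule: TauStarRule = "printed",
) -> DetectionResult:
    """Run the sequential predictive-interval criterion on a set of effects.

    Parameters
    ----------
    effects
        Per-gene mean treatment effects.
    prior
        NIG hyperparameters.  Defaults to the weakly-informative choice
        (mu0=0, lambda=0.01, tau=3) with beta derived from the full effect
        vector by ``default_beta``; a prior passed with ``beta=None`` has
        its beta filled the same way.
    alpha
        Two-sided level of the predictive interval (default 0.05).
    order
        ``"increasing"`` (default) visits genes in increasing numerical
        order of y.  ``"extremity"`` visits them by decreasing \\|y\\| — a
        non-default variant for sensitivity analysis, since the sequential
        exclusion makes the visiting order material.
    tau_star_rule
        Degrees-of-freedom update; ``"printed"`` (tau + n + 1, the default)
        or ``"standard"`` (tau + n, sensitivity analysis only).

    Returns
    -------
    DetectionResult with calls, per-gene thresholds and the processing order
    mapped back to the original gene order.
    """
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must lie in (0, 1), got {alpha}")
    y = effects.y
    n = y.size
    if n < 3:
        raise ValidationError(f"sequential detection needs >= 3 genes, got {n}")

    if prior is None:
        prior = NIGHyperparams()
    beta = prior.beta if prior.beta is not None else default_beta(y, prior.tau)
    mu0, lam, tau = prior.mu0, prior.lam, prior.tau

    if order == "increasing":
        visit = np.argsort(y, kind="stable")
    elif order == "extremity":
        visit = np.argsort(-np.abs(y), kind="stable")
    else:
        raise ValidationError(f"unknown processing order: {order!r}")

    tq = _TQuantileCache(1 - alpha / 2)

    # Pool state over the not-yet-called genes: count, sum, sum of squares.
    # The current gene is removed for its own step and restored unless called.
    m = n
    s1 = float(np.sum(y))
    s2 = float(np.sum(y * y))

    called = np.zeros(n, dtype=bool)
    threshold = np.empty(n, dtype=float)
    mu_star_diag = np.empty(n, dtype=float)

    for step, g in enumerate(visit):
        v = float(y[g])
        mr = m - 1
        if mr < 2:
            raise InsufficientDataError(
                f"reference set exhausted at step {step}: only {mr} effects remain "
                "uncalled (nearly every gene was called differential)"
            )
        s1r = s1 - v
        s2r = s2 - v * v
        ybar = s1r / mr
        var_num = s2r - mr * ybar * ybar
        samp_var = var_num / (mr - 1) if var_num > 0.0 else 0.0

        tau_star = tau + mr + 1 if tau_star_rule == "printed" else tau + mr
        beta_star = beta + (mr - 1) * samp_var + mr * lam * (ybar - mu0) ** 2 / (mr + lam)
        pred_var = (tau_star / (tau_star - 2)) * (
            beta_star * (mr + lam + 1) / (tau_star * (mr + lam))
        )
        thr = tq(tau_star) * math.sqrt(pred_var)

        threshold[g] = thr
        mu_star_diag[g] = (mr / (mr + lam)) * ybar + (lam / (mr + lam)) * mu0
        if abs(v) > thr:
            called[g] = True
            m, s1, s2 = mr, s1r, s2r  # gene leaves the pool for good

    return DetectionResult(
        gene_ids=list(effects.gene_ids),
        y=y.copy(),
        called=called,
        threshold=threshold,
        order=visit,
        method_name="pa",
        mu_star=mu_star_diag,
    )
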
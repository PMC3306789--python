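"""Independent scalar oracles used across the test suite.

Everything here is written with plain Python loops and from-scratch
recomputation at every step, deliberately avoiding the vectorised /
incremental code paths it is used to check.
"""

from __future__ import annotations

import math

from scipy import stats


def sequential_pa_oracle(
    y,
    mu0: float = 0.0,
    lam: float = 1e-2,
    tau: float = 3.0,
    alpha: float = 0.05,
    beta: float | None = None,
):
    """From-scratch re-execution of the sequential predictive criterion.

    Visits genes in increasing order of y (ties by original index), rebuilds
    the reference set and recomputes mean, variance, beta*, tau* and the
    predictive variance with scalar loops at every step.  Returns
    (called: set of original indices, thresholds: dict index -> threshold).
    """
    y = [float(v) for v in y]
    n = len(y)
    order = sorted(range(n), key=lambda i: (y[i], i))
    if beta is None:
        r = max(y) - min(y)
        beta = (tau - 2.0) * r * r
    called: set[int] = set()
    thresholds: dict[int, float] = {}
    for g in order:
        ref = [y[j] for j in order if j != g and j not in called]
        m = len(ref)
        assert m >= 2, "oracle reference set exhausted"
        ybar = sum(ref) / m
        s2 = sum((v - ybar) ** 2 for v in ref) / (m - 1)
        tau_s = tau + m + 1
        beta_s = beta + (m - 1) * s2 + m * lam * (ybar - mu0) ** 2 / (m + lam)
        var = (tau_s / (tau_s - 2.0)) * (beta_s * (m + lam + 1.0) / (tau_s * (m + lam)))
        thr = float(stats.t.ppf(1 - alpha / 2, tau_s)) * math.sqrt(var)
        thresholds[g] = thr
        if abs(y[g]) > thr:
            called.add(g)
    return called, thresholds


def confusion_counts_oracle(truth, called):
    """Plain counting loop over a truth/calls pair."""
    tp = fp = fn = tn = 0
    for t, c in zip(truth, called, strict=True):
        if t and c:
            tp += 1
        elif t and not c:
            fn += 1
        elif not t and c:
            fp += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def t_upper_quantile_oracle(q: float, df: float, tol: float = 1e-10) -> float:
    """Student-t quantile by numerically integrated CDF inverted by bisection.

    The pdf is written out from the gamma-function form and integrated with
    fixed-order Gauss-Legendre panels; no scipy distribution code is used.
    """
    import numpy as np

    lognorm = (
        math.lgamma((df + 1) / 2.0) - math.lgamma(df / 2.0) - 0.5 * math.log(df * math.pi)
    )

    def pdf(x):
        return math.exp(lognorm - ((df + 1) / 2.0) * math.log1p(x * x / df))

    nodes, weights = np.polynomial.legendre.leggauss(80)

    def cdf(x: float) -> float:
        # 0.5 + integral of the symmetric pdf from 0 to x, panelled.
        total = 0.0
        n_panels = max(1, int(abs(x)) + 1)
        edges = [x * k / n_panels for k in range(n_panels + 1)]
        for a, b in zip(edges[:-1], edges[1:]):
            mid, half = (a + b) / 2.0, (b - a) / 2.0
            total += half * sum(w * pdf(mid + half * t) for t, w in zip(nodes, weights))
        return 0.5 + total

    lo, hi = 0.0, 1.0
    while cdf(hi) < q:
        hi *= 2.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if cdf(mid) < q:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0
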
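"""Per-gene two-sample tests: Welch t, Cyber-t, and the Bayesian t-test.

All three compare the replicate means of one gene between conditions and
differ only in how the standard error in the denominator is estimated:

* Welch t (TT): per-gene sample variances, Welch-Satterthwaite fractional
  degrees of freedom.
* Cyber-t (CT): variances shrunk towards a per-gene prior variance
  sigma0^2 = ((n_g-1)/n_g) s_g^2 (s_g^2 pooled over both conditions) with
  nu0 = k - n_g pseudo-observations, k = 10.
* Bayesian t (BTT): posterior t for the mean difference with nu0 = n_g and
  sigma0^2 = s_g^2, i.e. a single pooled-and-shrunk variance.

Vectorised ``*_matrix`` variants evaluate a whole genes-by-replicates
matrix at once; the scalar functions wrap them for a single gene and attach
the decision at a working level alpha.  P-values are two-sided throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, ValidationError

__all__ = [
    "GeneTestResult",
    "welch_t_test",
    "cyber_t_test",
    "bayes_t_test",
    "welch_t_matrix",
    "cyber_t_matrix",
    "bayes_t_matrix",
    "BASELINE_MATRIX_TESTS",
]

CYBER_T_K = 10  # total pseudo+real observations the CT variance prior assumes


@dataclass(frozen=True)
class GeneTestResult:
    """Outcome of one per-gene test at a working level alpha."""

    gene_id: str
    statistic: float
    df: float
    p_value: float
    called: bool


def _check_pair(ctrl, trt) -> tuple[np.ndarray, np.ndarray]:
    c = np.asarray(ctrl, dtype=float)
    t = np.asarray(trt, dtype=float)
    if c.ndim == 1:
        c = c[None, :]
    if t.ndim == 1:
        t = t[None, :]
    if c.shape[0] != t.shape[0]:
        raise ValidationError(
            f"control and treatment gene counts differ: {c.shape[0]} vs {t.shape[0]}"
        )
    if c.shape[1] < 2 or t.shape[1] < 2:
        raise ValidationError("each condition needs >= 2 replicates")
    if not (np.all(np.isfinite(c)) and np.all(np.isfinite(t))):
        raise ValidationError("non-finite expression value in test input")
    return c, t


def _two_sided_p(stat: np.ndarray, df: np.ndarray) -> np.ndarray:
    return 2.0 * stats.t.sf(np.abs(stat), df)


def welch_t_matrix(ctrl, trt) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Welch t statistic, Welch-Satterthwaite df and two-sided p per row."""
    c, t = _check_pair(ctrl, trt)
    nc, nt = c.shape[1], t.shape[1]
    vc = c.var(axis=1, ddof=1)
    vt = t.var(axis=1, ddof=1)
    se2 = vc / nc + vt / nt
    if np.any(se2 == 0.0):
        raise DegenerateDataError("both sample variances zero: Welch t undefined")
    stat = (t.mean(axis=1) - c.mean(axis=1)) / np.sqrt(se2)
    df = se2**2 / ((vc / nc) ** 2 / (nc - 1) + (vt / nt) ** 2 / (nt - 1))
    return stat, df, _two_sided_p(stat, df)


def cyber_t_matrix(ctrl, trt, k: int = CYBER_T_K) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cyber-t statistic with per-gene prior variance, df = nu0 + n_g - 2.

    nu0 = max(k - n_g, 0); sigma0^2 = ((n_g-1)/n_g) s_g^2 where s_g^2 is the
    sample variance of the pooled two-condition vector.  The shrunk
    per-condition variance is

        sigma~_h^2 = (nu0 sigma0^2 + (n_h - 1) s_h^2) / (nu0 + n_h - 2).
    """
    c, t = _check_pair(ctrl, trt)
    nc, nt = c.shape[1], t.shape[1]
    ng = nc + nt
    nu0 = max(k - ng, 0)
    if nu0 + nc - 2 <= 0 or nu0 + nt - 2 <= 0:
        raise ValidationError(
            f"Cyber-t undefined: nu0 + n_h - 2 <= 0 (nu0={nu0}, n_c={nc}, n_t={nt})"
        )
    pooled = np.concatenate([c, t], axis=1)
    s2g = pooled.var(axis=1, ddof=1)
    sigma0_2 = ((ng - 1) / ng) * s2g
    vc = (nu0 * sigma0_2 + (nc - 1) * c.var(axis=1, ddof=1)) / (nu0 + nc - 2)
    vt = (nu0 * sigma0_2 + (nt - 1) * t.var(axis=1, ddof=1)) / (nu0 + nt - 2)
    se2 = vt / nt + vc / nc
    if np.any(se2 == 0.0):
        raise DegenerateDataError("shrunk variances zero: Cyber-t undefined")
    stat = (t.mean(axis=1) - c.mean(axis=1)) / np.sqrt(se2)
    df = np.full(stat.shape, float(nu0 + nc + nt - 2))
    return stat, df, _two_sided_p(stat, df)


def bayes_t_matrix(ctrl, trt) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bayesian t-test statistic with nu0 = n_g, sigma0^2 = s_g^2.

    The posterior of the mean difference is Student t with

        nu_n = nu0 + n_c + n_t - 2,
        nu_n sigma_n^2 = nu0 sigma0^2 + (n_c-1) s_c^2 + (n_t-1) s_t^2,

    and the statistic is (xbar_t - xbar_c) / (sigma_n sqrt(1/n_t + 1/n_c)).
    """
    c, t = _check_pair(ctrl, trt)
    nc, nt = c.shape[1], t.shape[1]
    ng = nc + nt
    nu0 = ng
    pooled = np.concatenate([c, t], axis=1)
    sigma0_2 = pooled.var(axis=1, ddof=1)
    nu_n = nu0 + nc + nt - 2
    sigma_n2 = (
        nu0 * sigma0_2 + (nc - 1) * c.var(axis=1, ddof=1) + (nt - 1) * t.var(axis=1, ddof=1)
    ) / nu_n
    if np.any(sigma_n2 == 0.0):
        raise DegenerateDataError("posterior variance zero: Bayesian t undefined")
    stat = (t.mean(axis=1) - c.mean(axis=1)) / np.sqrt(sigma_n2 * (1.0 / nt + 1.0 / nc))
    df = np.full(stat.shape, float(nu_n))
    return stat, df, _two_sided_p(stat, df)


def _scalar(matrix_fn, ctrl, trt, alpha: float, gene_id: str, **kw) -> GeneTestResult:
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must lie in (0, 1), got {alpha}")
    stat, df, p = matrix_fn(np.atleast_2d(ctrl), np.atleast_2d(trt), **kw)
    p0 = float(p[0])
    return GeneTestResult(
        gene_id=gene_id,
        statistic=float(stat[0]),
        df=float(df[0]),
        p_value=min(p0, 1.0),
        called=bool(p0 < alpha),
    )


def welch_t_test(ctrl, trt, alpha: float = 0.05, gene_id: str = "") -> GeneTestResult:
    """Welch two-sample t-test for one gene (two-sided)."""
    return _scalar(welch_t_matrix, ctrl, trt, alpha, gene_id)


def cyber_t_test(
    ctrl, trt, alpha: float = 0.05, gene_id: str = "", k: int = CYBER_T_K
) -> GeneTestResult:
    """Cyber-t test for one gene (two-sided), per-gene prior variance."""
    return _scalar(cyber_t_matrix, ctrl, trt, alpha, gene_id, k=k)


def bayes_t_test(ctrl, trt, alpha: float = 0.05, gene_id: str = "") -> GeneTestResult:
    """Bayesian t-test for one gene (two-sided)."""
    return _scalar(bayes_t_matrix, ctrl, trt, alpha, gene_id)


#: Matrix-level entry points keyed by the short method labels used in
#: benchmarking and on the command line.
BASELINE_MATRIX_TESTS = {
    "tt": welch_t_matrix,
    "ct": cyber_t_matrix,
    "btt": bayes_t_matrix,
}
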
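"""Scoring detector calls against ground truth and Monte-Carlo benchmarking.

``score_calls`` reduces one replicate to the three rates used throughout
the study:

* TPR — called-and-true over true (the per-replicate power),
* FPR — called-and-null over null (the per-replicate type-I error),
* TDR — called-and-true over called (the precision; undefined when nothing
  is called, and such replicates are dropped from the TDR mean).

``run_benchmark`` runs every requested method on the *same* simulated
dataset within each replicate (a paired design, which shrinks the Monte
Carlo variance of method contrasts) and aggregates the rates per scenario
cell with their Monte-Carlo standard errors.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .baselines import BASELINE_MATRIX_TESTS
from .dataset import compute_treatment_effects
from .errors import ValidationError
from .pa import pa_detect
from .predictive import NIGHyperparams
from .simulate import LabeledDataset, ScenarioConfig, simulate_dataset

__all__ = ["MetricSet", "BenchmarkReport", "score_calls", "run_benchmark"]

METHODS = ("pa", "tt", "ct", "btt")

SCENARIO_COLS = ["n", "n_c", "n_t", "p_over", "p_under", "delta", "gamma"]


@dataclass(frozen=True)
class MetricSet:
    """Confusion-matrix rates of one replicate."""

    tpr: float
    fpr: float
    tdr: float | None
    n_true: int
    n_called: int


@dataclass(frozen=True)
class BenchmarkReport:
    """Aggregated rates per (scenario, method) cell.

    ``cells`` has one row per (scenario, method) with columns
    ``tpr_mean, tpr_se, fpr_mean, fpr_se, tdr_mean, tdr_se, n_reps,
    n_reps_tdr``.  ``replicates`` (optional) keeps the per-replicate rates
    plus a dataset checksum shared by all methods of a replicate.
    """

    cells: pd.DataFrame
    replicates: pd.DataFrame | None = None

    def lookup(self, method: str, **scenario) -> pd.Series:
        """The single aggregated row matching ``method`` and scenario keys."""
        df = self.cells[self.cells["method"] == method]
        for key, val in scenario.items():
            df = df[df[key] == val]
        if len(df) != 1:
            raise KeyError(f"expected exactly one cell, found {len(df)}")
        return df.iloc[0]


def score_calls(truth, called) -> MetricSet:
    """Score a boolean call vector against 0/1 ground truth."""
    t = np.asarray(truth, dtype=int).ravel()
    c = np.asarray(called, dtype=bool).ravel()
    if t.size != c.size:
        raise ValidationError(f"length mismatch: truth {t.size}, calls {c.size}")
    n_true = int(t.sum())
    n_null = t.size - n_true
    if n_true == 0 or n_null == 0:
        raise ValidationError("truth must contain at least one 1 and one 0")
    tp = int(np.count_nonzero(c & (t == 1)))
    fp = int(np.count_nonzero(c & (t == 0)))
    n_called = tp + fp
    return MetricSet(
        tpr=tp / n_true,
        fpr=fp / n_null,
        tdr=(tp / n_called) if n_called > 0 else None,
        n_true=n_true,
        n_called=n_called,
    )


def _dataset_hash(labeled: LabeledDataset) -> str:
    h = hashlib.blake2b(digest_size=8)
    h.update(np.ascontiguousarray(labeled.data.control).tobytes())
    h.update(np.ascontiguousarray(labeled.data.treatment).tobytes())
    return h.hexdigest()


def _run_methods_on(
    labeled: LabeledDataset,
    methods: Sequence[str],
    alpha: float,
    prior: NIGHyperparams | None,
) -> dict[str, np.ndarray]:
    """Boolean call vectors of every requested method on one dataset."""
    calls: dict[str, np.ndarray] = {}
    effects = None
    for m in methods:
        if m == "pa":
            if effects is None:
                effects = compute_treatment_effects(labeled.data)
            calls["pa"] = pa_detect(effects, prior=prior, alpha=alpha).called
        elif m in BASELINE_MATRIX_TESTS:
            _, _, p = BASELINE_MATRIX_TESTS[m](labeled.data.control, labeled.data.treatment)
            calls[m] = p < alpha
        else:
            raise ValidationError(f"unknown method: {m!r} (expected one of {METHODS})")
    return calls


def _mean_se(values: Iterable[float]) -> tuple[float, float, int]:
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        return (float("nan"), float("nan"), 0)
    se = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
    return (float(arr.mean()), se, int(arr.size))


def run_benchmark(
    grid: Sequence[ScenarioConfig] | ScenarioConfig,
    methods: Sequence[str] = METHODS,
    alpha: float = 0.05,
    prior: NIGHyperparams | None = None,
    keep_replicates: bool = False,
    progress: Callable[[str], None] | None = None,
) -> BenchmarkReport:
    """Simulate every scenario cell, run all methods, aggregate the rates.

    For each scenario, ``cfg.n_reps`` independent datasets are generated;
    all methods are evaluated on the same dataset within a replicate.  The
    TDR mean skips replicates with zero discoveries.
    """
    if isinstance(grid, ScenarioConfig):
        grid = [grid]
    bad = [m for m in methods if m not in METHODS]
    if bad:
        raise ValidationError(f"unknown methods: {bad}")

    cell_rows: list[dict] = []
    rep_rows: list[dict] = []
    for ci, cfg in enumerate(grid):
        per_method: dict[str, list[MetricSet]] = {m: [] for m in methods}
        for rep in range(cfg.n_reps):
            labeled = simulate_dataset(cfg, rep)
            calls = _run_methods_on(labeled, methods, alpha, prior)
            dhash = _dataset_hash(labeled) if keep_replicates else None
            for m in methods:
                ms = score_calls(labeled.truth, calls[m])
                per_method[m].append(ms)
                if keep_replicates:
                    rep_rows.append(
                        {
                            **{k: getattr(cfg, k) for k in SCENARIO_COLS},
                            "rep": rep,
                            "method": m,
                            "tpr": ms.tpr,
                            "fpr": ms.fpr,
                            "tdr": ms.tdr,
                            "n_called": ms.n_called,
                            "dataset_hash": dhash,
                        }
                    )
        for m in methods:
            sets = per_method[m]
            tpr_mean, tpr_se, n_reps = _mean_se(s.tpr for s in sets)
            fpr_mean, fpr_se, _ = _mean_se(s.fpr for s in sets)
            tdr_mean, tdr_se, n_tdr = _mean_se(s.tdr for s in sets if s.tdr is not None)
            cell_rows.append(
                {
                    **{k: getattr(cfg, k) for k in SCENARIO_COLS},
                    "method": m,
                    "tpr_mean": tpr_mean,
                    "tpr_se": tpr_se,
                    "fpr_mean": fpr_mean,
                    "fpr_se": fpr_se,
                    "tdr_mean": tdr_mean,
                    "tdr_se": tdr_se,
                    "n_reps": n_reps,
                    "n_reps_tdr": n_tdr,
                }
            )
        if progress is not None:
            progress(
                f"cell {ci + 1}/{len(grid)}: n={cfg.n_c} delta={cfg.delta} "
                f"gamma={cfg.gamma} p={cfg.p_over}+{cfg.p_under}"
            )

    cells = pd.DataFrame(cell_rows)
    reps = pd.DataFrame(rep_rows) if keep_replicates else None
    return BenchmarkReport(cells=cells, replicates=reps)


def to_wide(report: BenchmarkReport, metric: str = "tpr") -> pd.DataFrame:
    """Pivot a report to the study's table layout: one row per
    (sample size, p-split, gamma, method), one column per delta."""
    col = f"{metric}_mean"
    if col not in report.cells.columns:
        raise ValidationError(f"unknown metric: {metric!r}")
    return report.cells.pivot_table(
        index=["n_c", "n_t", "p_over", "p_under", "gamma", "method"],
        columns="delta",
        values=col,
    )
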
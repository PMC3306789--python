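"""Artificial two-condition expression data with known differential genes.

Each simulated dataset mimics a bulk log-expression experiment: every gene's
control replicates are N(mu_c, sigma_c^2) with mu_c = -14 and
sigma_c^2 = 0.8 by default (the observed average log-scale mean and variance
of the control condition in a classical E. coli membrane-array experiment).
A fixed fraction p% of the genes is differential: their treatment
replicates are drawn with the mean shifted by +/- delta * sigma_c
(over-/under-expressed) and the standard deviation scaled by gamma,

    treatment ~ N(mu_c +/- delta * sigma_c, (gamma * sigma_c)^2),

while all other genes' treatment replicates are distributed exactly like
control.  Values are generated directly on the log scale.

The differential-gene count is deterministic (exactly round(n*p/100), split
into over and under parts); only the subset membership is random, redrawn
independently for every replicate.  Each (seed, replicate) pair maps to an
independent, reproducible random substream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dataset import ExpressionDataset
from .errors import ValidationError

__all__ = ["ScenarioConfig", "LabeledDataset", "simulate_dataset", "scenario_grid"]

#: The simulation-grid axes used throughout the benchmarking study.
GRID_DELTAS = (0.0, 0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 1.75, 2.0)
GRID_GAMMAS = (1.0, 2.0, 3.0)
GRID_P_SPLITS = ((3.0, 2.0), (7.0, 3.0), (5.0, 15.0))
GRID_SAMPLE_SIZES = (4, 8)


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the simulation design.

    delta shifts the treatment mean in control-s.d. units; gamma scales the
    treatment s.d.; p_over/p_under are percentages of the n genes simulated
    as over-/under-expressed.
    """

    n: int = 1000
    n_c: int = 4
    n_t: int = 4
    mu_c: float = -14.0
    sigma2_c: float = 0.8
    p_over: float = 3.0
    p_under: float = 2.0
    delta: float = 0.0
    gamma: float = 1.0
    n_reps: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2 or self.n_c < 2 or self.n_t < 2:
            raise ValidationError("need n >= 2 genes and >= 2 replicates per condition")
        if not self.sigma2_c > 0:
            raise ValidationError(f"sigma2_c must be positive, got {self.sigma2_c}")
        if self.p_over < 0 or self.p_under < 0 or self.p_over + self.p_under >= 100:
            raise ValidationError(
                f"need 0 <= p_over + p_under < 100, got {self.p_over} + {self.p_under}"
            )
        if self.delta < 0:
            raise ValidationError(f"delta must be >= 0, got {self.delta}")
        if self.gamma < 0:
            raise ValidationError(f"gamma must be >= 0, got {self.gamma}")
        if self.n_reps < 1:
            raise ValidationError("n_reps must be >= 1")

    @property
    def sigma_c(self) -> float:
        return math.sqrt(self.sigma2_c)

    @property
    def n_over(self) -> int:
        return round(self.n * self.p_over / 100.0)

    @property
    def n_under(self) -> int:
        return round(self.n * self.p_under / 100.0)


@dataclass(frozen=True)
class LabeledDataset:
    """Simulated dataset plus its ground-truth differential labels."""

    data: ExpressionDataset
    truth: np.ndarray = field(repr=False)  # 1 = simulated with difference
    direction: np.ndarray = field(repr=False)  # "over" | "under" | "none"

    def __post_init__(self) -> None:
        truth = np.asarray(self.truth, dtype=int)
        direction = np.asarray(self.direction, dtype=object)
        object.__setattr__(self, "truth", truth)
        object.__setattr__(self, "direction", direction)
        n = self.data.n_genes
        if truth.size != n or direction.size != n:
            raise ValidationError("truth/direction length must equal the gene count")
        if not np.array_equal(direction == "none", truth == 0):
            raise ValidationError("direction == 'none' must coincide with truth == 0")


def _rng_for(cfg: ScenarioConfig, rep_index: int) -> np.random.Generator:
    # One independent substream per (scenario seed, replicate): any single
    # replicate can be regenerated in isolation.
    ss = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(rep_index,))
    return np.random.default_rng(ss)


def simulate_dataset(cfg: ScenarioConfig, rep_index: int = 0) -> LabeledDataset:
    """Generate one labelled dataset for the given scenario and replicate."""
    rng = _rng_for(cfg, rep_index)
    n, sc = cfg.n, cfg.sigma_c
    n_over, n_under = cfg.n_over, cfg.n_under

    perm = rng.permutation(n)
    over_idx = perm[:n_over]
    under_idx = perm[n_over : n_over + n_under]

    control = rng.normal(cfg.mu_c, sc, size=(n, cfg.n_c))
    treatment = rng.normal(cfg.mu_c, sc, size=(n, cfg.n_t))
    if n_over:
        treatment[over_idx] = rng.normal(
            cfg.mu_c + cfg.delta * sc, cfg.gamma * sc, size=(n_over, cfg.n_t)
        )
    if n_under:
        treatment[under_idx] = rng.normal(
            cfg.mu_c - cfg.delta * sc, cfg.gamma * sc, size=(n_under, cfg.n_t)
        )

    truth = np.zeros(n, dtype=int)
    truth[over_idx] = 1
    truth[under_idx] = 1
    direction = np.full(n, "none", dtype=object)
    direction[over_idx] = "over"
    direction[under_idx] = "under"

    width = max(4, len(str(n)))
    gene_ids = [f"g{i + 1:0{width}d}" for i in range(n)]
    data = ExpressionDataset(gene_ids=gene_ids, control=control, treatment=treatment)
    return LabeledDataset(data=data, truth=truth, direction=direction)


def scenario_grid(
    sample_sizes: Sequence[int] = GRID_SAMPLE_SIZES,
    p_splits: Sequence[tuple[float, float]] = GRID_P_SPLITS,
    deltas: Sequence[float] = GRID_DELTAS,
    gammas: Sequence[float] = GRID_GAMMAS,
    n_reps: int = 100,
    seed: int = 0,
    **common,
) -> list[ScenarioConfig]:
    """The full factorial simulation grid with deterministic derived seeds.

    With the default axes this yields 2 sample sizes x 3 p-splits x 9 deltas
    x 3 gammas = 162 scenario cells, each carrying its own distinct seed
    derived reproducibly from ``seed``.
    """
    configs: list[ScenarioConfig] = []
    i = 0
    for size in sample_sizes:
        for p_over, p_under in p_splits:
            for gamma in gammas:
                for delta in deltas:
                    child = np.random.SeedSequence(entropy=seed, spawn_key=(i,))
                    cell_seed = int(child.generate_state(1)[0] % (2**31))
                    configs.append(
                        ScenarioConfig(
                            n_c=size,
                            n_t=size,
                            p_over=p_over,
                            p_under=p_under,
                            delta=delta,
                            gamma=gamma,
                            n_reps=n_reps,
                            seed=cell_seed,
                            **common,
                        )
                    )
                    i += 1
    return configs
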
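"""Two-condition expression data and per-gene mean treatment effects.

The containers here hold log-scale expression measurements for ``n`` genes
replicated ``n_c`` times under a control condition and ``n_t`` times under a
treatment condition, and the derived per-gene *sampled mean treatment
effect*

    y_g = mean(treatment row g) - mean(control row g),

the quantity all downstream detectors operate on.  Input is assumed already
log-transformed and normalised; no transformation is applied here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = ["ExpressionDataset", "TreatmentEffects", "compute_treatment_effects"]


def _as_matrix(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 2:
        raise ValidationError(f"{name} matrix must be 2-dimensional, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class ExpressionDataset:
    """Log-expression measurements for n genes under two conditions.

    Parameters
    ----------
    gene_ids
        Unique string identifiers, one per gene (row).
    control, treatment
        ``(n, n_c)`` and ``(n, n_t)`` float matrices of log-expression
        values.  Every entry must be finite; at least two replicates per
        condition are required so that sample variances exist.
    """

    gene_ids: list[str]
    control: np.ndarray = field(repr=False)
    treatment: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", [str(g) for g in self.gene_ids])
        object.__setattr__(self, "control", _as_matrix(self.control, "control"))
        object.__setattr__(self, "treatment", _as_matrix(self.treatment, "treatment"))

        n = len(self.gene_ids)
        if n < 2:
            raise ValidationError(f"need at least 2 genes, got {n}")
        if len(set(self.gene_ids)) != n:
            seen: set[str] = set()
            dup = next(g for g in self.gene_ids if g in seen or seen.add(g))
            raise ValidationError(f"duplicate gene id: {dup!r}")
        for name, mat in (("control", self.control), ("treatment", self.treatment)):
            if mat.shape[0] != n:
                raise ValidationError(
                    f"{name} matrix has {mat.shape[0]} rows for {n} gene ids"
                )
            if mat.shape[1] < 2:
                raise ValidationError(
                    f"{name} needs >= 2 replicates, got {mat.shape[1]}"
                )
            bad = ~np.isfinite(mat)
            if bad.any():
                g = self.gene_ids[int(np.where(bad.any(axis=1))[0][0])]
                raise ValidationError(f"non-finite value in {name} row for gene {g!r}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_control(self) -> int:
        return self.control.shape[1]

    @property
    def n_treatment(self) -> int:
        return self.treatment.shape[1]


@dataclass(frozen=True)
class TreatmentEffects:
    """Per-gene mean treatment effects y_g (treatment minus control mean)."""

    gene_ids: list[str]
    y: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float).ravel()
        object.__setattr__(self, "y", y)
        if len(self.gene_ids) != y.size:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids but {y.size} effect values"
            )
        if not np.all(np.isfinite(y)):
            g = self.gene_ids[int(np.flatnonzero(~np.isfinite(y))[0])]
            raise ValidationError(f"non-finite treatment effect for gene {g!r}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def compute_treatment_effects(data: ExpressionDataset) -> TreatmentEffects:
    """Per-gene difference of replicate means, treatment minus control.

    Gene order is preserved from the input dataset.
    """
    y = data.treatment.mean(axis=1) - data.control.mean(axis=1)
    return TreatmentEffects(gene_ids=list(data.gene_ids), y=y)
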
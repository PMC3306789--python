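"""Delimited-table readers and writers shared by the library and the CLI.

The expression-table dialect is a header row followed by one row per gene:
column 1 the gene identifier, then the replicate columns.  Condition
membership comes either from column-name prefixes ("c1", "c2", ... control;
"t1", "t2", ... treatment) or from an explicit two-column design file
(sample name, condition in {control, treatment}).  Tab and comma delimiters
are auto-detected; output is always tab-separated with floats at six
significant digits.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .baselines import GeneTestResult
from .dataset import ExpressionDataset
from .errors import ValidationError
from .evaluate import BenchmarkReport, to_wide
from .pa import DetectionResult
from .simulate import LabeledDataset

__all__ = [
    "read_expression_table",
    "read_design",
    "read_truth",
    "write_results",
    "write_expression_table",
    "write_truth",
]

FLOAT_FMT = "%.6g"


def _detect_sep(path: Path) -> str:
    with open(path, "r", newline="") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_design(path: str | Path) -> dict[str, str]:
    """Read a sample -> condition mapping (two columns, no header required)."""
    path = Path(path)
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValidationError(f"design file {path} needs two columns (sample, condition)")
    # Tolerate an optional header line.
    first = df.iloc[0, 1].strip().lower()
    if first not in ("control", "treatment"):
        df = df.iloc[1:]
    design: dict[str, str] = {}
    for i, row in df.iterrows():
        sample, cond = str(row.iloc[0]).strip(), str(row.iloc[1]).strip().lower()
        if cond not in ("control", "treatment"):
            raise ValidationError(
                f"design file {path}, line {int(i) + 1}: condition must be "
                f"'control' or 'treatment', got {cond!r}"
            )
        if sample in design:
            raise ValidationError(f"design file {path}: duplicate sample {sample!r}")
        design[sample] = cond
    return design


def _split_columns(
    columns: Sequence[str], design: Mapping[str, str] | None
) -> tuple[list[str], list[str]]:
    ctrl, trt = [], []
    for col in columns:
        if design is not None:
            if col not in design:
                raise ValidationError(f"sample column {col!r} missing from design file")
            cond = design[col]
        else:
            low = col.strip().lower()
            if low.startswith("c"):
                cond = "control"
            elif low.startswith("t"):
                cond = "treatment"
            else:
                raise ValidationError(
                    f"cannot assign column {col!r} to a condition: name does not "
                    "start with 'c' or 't' and no design file was given"
                )
        (ctrl if cond == "control" else trt).append(col)
    return ctrl, trt


def read_expression_table(
    path: str | Path,
    design: str | Path | Mapping[str, str] | None = None,
    log2: bool = False,
) -> ExpressionDataset:
    """Read a delimited expression matrix into an :class:`ExpressionDataset`.

    Parameters
    ----------
    path
        Delimited text table, header row, gene identifiers in column 1.
    design
        Optional design-file path or sample->condition mapping; without it,
        column names must start with 'c' (control) or 't' (treatment).
    log2
        Apply log2 to all values on read (off by default: input is assumed
        already on the log scale).
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    if design is not None and not isinstance(design, Mapping):
        design = read_design(design)
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, dtype={0: str})
    if df.shape[1] < 5:
        raise ValidationError(
            f"{path}: need a gene column plus >= 2 replicates per condition"
        )
    gene_ids = df.iloc[:, 0].tolist()
    dup = pd.Series(gene_ids)
    if dup.duplicated().any():
        first_dup = dup[dup.duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicated gene id {first_dup!r}")

    value_cols = list(df.columns[1:])
    ctrl_cols, trt_cols = _split_columns(value_cols, design)
    if len(ctrl_cols) < 2 or len(trt_cols) < 2:
        raise ValidationError(
            f"{path}: need >= 2 replicates per condition, got "
            f"{len(ctrl_cols)} control / {len(trt_cols)} treatment"
        )

    values = df[value_cols].apply(pd.to_numeric, errors="coerce")
    bad = values.isna()
    if bad.to_numpy().any():
        row = int(np.flatnonzero(bad.any(axis=1).to_numpy())[0])
        raise ValidationError(
            f"{path}, data line {row + 2}: missing or non-numeric value "
            f"for gene {gene_ids[row]!r}"
        )
    control = values[ctrl_cols].to_numpy(dtype=float)
    treatment = values[trt_cols].to_numpy(dtype=float)
    if log2:
        control = np.log2(control)
        treatment = np.log2(treatment)
    return ExpressionDataset(gene_ids=gene_ids, control=control, treatment=treatment)


def write_expression_table(labeled_or_data, path: str | Path) -> None:
    """Write an expression matrix (or a labelled simulation) as TSV."""
    data = labeled_or_data.data if isinstance(labeled_or_data, LabeledDataset) else labeled_or_data
    cols = {"gene_id": data.gene_ids}
    for j in range(data.n_control):
        cols[f"c{j + 1}"] = data.control[:, j]
    for j in range(data.n_treatment):
        cols[f"t{j + 1}"] = data.treatment[:, j]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_truth(labeled: LabeledDataset, path: str | Path) -> None:
    """Write the two-column ground-truth file (gene_id, indicator)."""
    pd.DataFrame(
        {"gene_id": labeled.data.gene_ids, "truth": labeled.truth}
    ).to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), dtype={0: str})
    if df.shape[1] < 2:
        raise ValidationError(f"truth file {path} needs columns (gene_id, indicator)")
    return df


def _detection_frame(result: DetectionResult) -> pd.DataFrame:
    rank = np.empty(len(result.gene_ids), dtype=int)
    rank[result.order] = np.arange(len(result.gene_ids))
    return pd.DataFrame(
        {
            "gene_id": result.gene_ids,
            "y": result.y,
            "threshold": result.threshold,
            "called": result.called.astype(int),
            "processing_rank": rank,
        }
    )


def _gene_tests_frame(results: Sequence[GeneTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "statistic": [r.statistic for r in results],
            "df": [r.df for r in results],
            "p_value": [r.p_value for r in results],
            "called": [int(r.called) for r in results],
        }
    )


def _benchmark_frame(report: BenchmarkReport, wide: bool, metric: str) -> pd.DataFrame:
    if wide:
        return to_wide(report, metric=metric).reset_index()
    long = report.cells.melt(
        id_vars=[c for c in report.cells.columns if not c.endswith(("_mean", "_se"))],
        var_name="metric",
        value_name="value",
    )
    return long


def write_results(result, path: str | Path, *, wide: bool = False, metric: str = "tpr") -> None:
    """Write a detection result, per-gene test list or benchmark report.

    Output is TSV with a header row, deterministic column order and floats
    at six significant digits.  For a :class:`BenchmarkReport`, ``wide=True``
    renders one delta per column in the study's table layout.
    """
    if isinstance(result, DetectionResult):
        df = _detection_frame(result)
    elif isinstance(result, BenchmarkReport):
        df = _benchmark_frame(result, wide, metric)
    elif isinstance(result, pd.DataFrame):
        df = result
    elif isinstance(result, Sequence) and all(
        isinstance(r, GeneTestResult) for r in result
    ):
        df = _gene_tests_frame(list(result))
    else:
        raise ValidationError(f"cannot serialise object of type {type(result).__name__}")
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
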
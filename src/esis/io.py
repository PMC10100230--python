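"""Readers and writers for expression matrices, survival tables and results.

Expression matrices travel as delimited text (TSV by default) with a header
row and an id column; survival tables as CSV with ``sample_id,time,event``
columns.  Reading normalizes orientation to samples x genes, rejects missing
or non-numeric values with located errors, and drops zero-IQR (constant or
near-constant) genes the way real cohorts pre-exclude unexpressed probes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .screening import ScreeningResult
from .transforms import SurvivalSamples

__all__ = [
    "ExpressionMatrix",
    "read_expression",
    "write_expression",
    "read_survival",
    "write_survival",
    "write_screening_result",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True, eq=False)
class ExpressionMatrix:
    """A samples x genes numeric matrix with identifiers on both axes."""

    values: np.ndarray
    sample_ids: np.ndarray
    gene_ids: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        sample_ids = np.asarray(self.sample_ids).astype(str)
        gene_ids = np.asarray(self.gene_ids).astype(str)
        if values.ndim != 2 or values.shape != (sample_ids.size, gene_ids.size):
            raise ValueError("values shape must be (len(sample_ids), len(gene_ids))")
        for name, ids in (("sample", sample_ids), ("gene", gene_ids)):
            dupes = pd.Index(ids)[pd.Index(ids).duplicated()]
            if len(dupes):
                raise ValueError(f"duplicate {name} ids: {sorted(set(dupes))[:5]}")
        if not np.all(np.isfinite(values)):
            raise ValueError("expression values must be finite")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", sample_ids)
        object.__setattr__(self, "gene_ids", gene_ids)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(
    path,
    orientation: str = "samples_by_genes",
    drop_zero_iqr: bool = True,
) -> ExpressionMatrix:
    """Read a delimited expression matrix, normalizing to samples x genes.

    Zero-IQR columns (constant or nearly-unexpressed genes) are dropped with
    a logged count; missing or non-numeric cells are rejected with their
    row/column location.
    """
    path = Path(path)
    if orientation not in ("samples_by_genes", "genes_by_samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate identifiers in header or id column")
    non_numeric = df.columns[[not pd.api.types.is_numeric_dtype(t) for t in df.dtypes]]
    if len(non_numeric):
        raise ValueError(f"{path}: non-numeric values in column(s) {list(non_numeric)[:5]}")
    if df.isna().any().any():
        rows = df.index[df.isna().any(axis=1)]
        cols = df.columns[df.isna().any(axis=0)]
        raise ValueError(f"{path}: missing values at rows {list(rows)[:5]}, columns {list(cols)[:5]}")
    if orientation == "genes_by_samples":
        df = df.T

    values = df.to_numpy(dtype=float)
    gene_ids = df.columns.to_numpy()
    if drop_zero_iqr:
        q75, q25 = np.percentile(values, [75, 25], axis=0)
        keep = (q75 - q25) > 0
        dropped = int((~keep).sum())
        if dropped:
            logger.info("excluded %d gene(s) with zero interquartile range", dropped)
            values, gene_ids = values[:, keep], gene_ids[keep]
    if values.shape[1] == 0:
        raise ValueError(f"{path}: no genes left after zero-IQR filtering")
    return ExpressionMatrix(values=values, sample_ids=df.index.to_numpy(), gene_ids=gene_ids)


def write_expression(expr: ExpressionMatrix, path) -> None:
    path = Path(path)
    df = pd.DataFrame(expr.values, index=expr.sample_ids, columns=expr.gene_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep=_sep_for(path))


def read_survival(path, expression: ExpressionMatrix | None = None):
    """Read a ``sample_id,time,event`` CSV; align order to an expression matrix.

    Returns ``(samples, sample_ids)``.  Nonpositive times, event codes
    outside {0, 1} and ids that do not match the expression matrix raise
    errors naming the offenders.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    required = {"sample_id", "time", "event"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: needs columns {sorted(required)}, found {list(df.columns)}")
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids "
                         f"{sorted(df.loc[df['sample_id'].duplicated(), 'sample_id'])[:5]}")
    bad_time = df.loc[~(pd.to_numeric(df["time"], errors="coerce") > 0), "sample_id"]
    if len(bad_time):
        raise ValueError(f"{path}: nonpositive or non-numeric time for {list(bad_time)[:5]}")
    bad_event = df.loc[~df["event"].isin((0, 1)), "sample_id"]
    if len(bad_event):
        raise ValueError(f"{path}: event not in {{0,1}} for {list(bad_event)[:5]}")

    if expression is not None:
        table_ids = set(df["sample_id"])
        expr_ids = set(expression.sample_ids)
        if table_ids != expr_ids:
            missing = sorted(expr_ids - table_ids)[:5]
            extra = sorted(table_ids - expr_ids)[:5]
            raise ValueError(f"{path}: unmatched ids (missing {missing}, extra {extra})")
        df = df.set_index("sample_id").loc[expression.sample_ids].reset_index()
    samples = SurvivalSamples(df["time"].to_numpy(float), df["event"].to_numpy(int))
    return samples, df["sample_id"].to_numpy()


def write_survival(samples: SurvivalSamples, sample_ids, path) -> None:
    pd.DataFrame(
        {"sample_id": np.asarray(sample_ids).astype(str), "time": samples.y, "event": samples.delta}
    ).to_csv(Path(path), index=False)


def write_screening_result(result: ScreeningResult, path) -> None:
    """Serialize a ranked screening result as TSV (gene_id, score, rank, selected)."""
    p = result.scores.size
    rank = np.empty(p, dtype=int)
    rank[result.order] = np.arange(1, p + 1)
    selected = np.zeros(p, dtype=bool)
    selected[result.selected] = True
    df = pd.DataFrame(
        {
            "gene_id": result.gene_ids,
            "score": [format(s, ".17g") for s in result.scores],
            "rank": rank,
            "selected": selected.astype(int),
        }
    ).sort_values("rank")
    df.to_csv(Path(path), sep="\t", index=False)
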
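"""Expression-matrix and gene-annotation input/output.

Internal convention: expression values are stored as natural logs,
x_i(t_j) = ln eps_i(t_j), with sampling times in minutes, strictly
increasing and starting at 0.  Inputs may arrive on a linear scale
(raw intensities) or as log2 values (the usual RMA output); both are
converted on load.  Annotation coordinates are 0-based half-open
(BED convention).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCALE_TAGS = ("natural_log", "linear", "log2")


class ExpressionLoadError(ValueError):
    """Raised when an expression table violates the load contract."""


class AnnotationError(ValueError):
    """Raised when a gene annotation violates its contract."""


@dataclass
class ExpressionMatrix:
    """N genes x (T+1) ordered time points of natural-log expression.

    Attributes
    ----------
    gene_ids : list of str
        Unique row identifiers (probe-set or gene ids).
    times : np.ndarray
        Sampling times in minutes, strictly increasing, first = 0.
    values : np.ndarray
        Shape (N, T+1), natural-log expression ln(eps_i(t_j)).
    scale_tag : str
        Scale of the *source* data before conversion.
    """

    gene_ids: list
    times: np.ndarray
    values: np.ndarray
    scale_tag: str = "natural_log"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.scale_tag not in SCALE_TAGS:
            raise ExpressionLoadError(f"unknown scale_tag {self.scale_tag!r}")
        n, t = self.values.shape
        if len(self.gene_ids) != n:
            raise ExpressionLoadError("gene_ids length does not match values")
        if len(self.times) != t:
            raise ExpressionLoadError("times length does not match values")
        if n < 2 or t < 3:
            raise ExpressionLoadError(f"need N >= 2 genes and >= 3 time points, got {n} x {t}")
        if len(set(self.gene_ids)) != n:
            dupes = pd.Index(self.gene_ids)[pd.Index(self.gene_ids).duplicated()].tolist()
            raise ExpressionLoadError(f"duplicate gene ids: {sorted(set(dupes))[:10]}")
        if np.any(~np.isfinite(self.values)):
            raise ExpressionLoadError("non-finite expression values after load")
        if np.any(np.diff(self.times) <= 0):
            raise ExpressionLoadError("times must be strictly increasing")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    def linear(self) -> np.ndarray:
        """Expression on the linear scale, eps_i(t_j)."""
        return np.exp(self.values)

    def index_of_time(self, t_minutes: float) -> int:
        idx = np.nonzero(np.isclose(self.times, t_minutes))[0]
        if idx.size == 0:
            raise KeyError(f"time {t_minutes} min not in grid {self.times.tolist()}")
        return int(idx[0])

    def subset(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [pos[g] for g in gene_ids]
        return ExpressionMatrix(list(gene_ids), self.times.copy(), self.values[rows].copy(), "natural_log")


@dataclass
class GeneAnnotation:
    """Per-gene genomic intervals, 0-based half-open, sortable by (chrom, start)."""

    records: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: chrom, start, end, gene_id, optional strand, optional symbol

    def __post_init__(self):
        req = {"chrom", "start", "end", "gene_id"}
        if len(self.records) and not req.issubset(self.records.columns):
            raise AnnotationError(f"annotation missing columns {req - set(self.records.columns)}")
        if len(self.records):
            bad = self.records[self.records.start >= self.records.end]
            if len(bad):
                raise AnnotationError(f"start >= end for {bad.gene_id.tolist()[:10]}")
            if self.records.gene_id.duplicated().any():
                ids = self.records.gene_id[self.records.gene_id.duplicated()].tolist()
                raise AnnotationError(f"duplicate gene_id rows: {sorted(set(ids))[:10]}")

    def __len__(self) -> int:
        return len(self.records)

    def sorted(self) -> pd.DataFrame:
        """Records in chromosomal order; overlaps broken by (start, end, gene_id)."""
        return self.records.sort_values(["chrom", "start", "end", "gene_id"], kind="mergesort").reset_index(drop=True)


def _convert_to_ln(values: np.ndarray, scale_tag: str, gene_ids, times) -> np.ndarray:
    if scale_tag == "natural_log":
        return values
    if scale_tag == "log2":
        return values * math.log(2.0)
    # linear: the domain of ln requires strictly positive input
    bad = np.argwhere(values <= 0)
    if bad.size:
        r, c = bad[0]
        raise ExpressionLoadError(
            f"non-positive linear value {values[r, c]!r} at gene {gene_ids[r]!r}, time {times[c]!r} min"
        )
    return np.log(values)


def _parse_time_label(label: str) -> float:
    s = str(label).strip()
    if s and s[0] in "tT":
        s = s[1:]
    try:
        return float(s)
    except ValueError as exc:
        raise ExpressionLoadError(f"cannot parse time label {label!r} as minutes") from exc


def read_expression(path, scale_tag: str = "linear") -> ExpressionMatrix:
    """Read a TSV expression table (header: gene_id, t0, t10, ... minutes).

    Values are converted to natural log according to ``scale_tag``
    (``linear`` -> ln, ``log2`` -> x ln 2, ``natural_log`` -> unchanged).
    Row order is preserved.  Non-numeric cells, duplicate gene ids and
    non-increasing times abort the load with a row/column report.
    """
    if scale_tag not in SCALE_TAGS:
        raise ExpressionLoadError(f"unknown scale_tag {scale_tag!r}")
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 4:
        raise ExpressionLoadError("need a gene_id column plus >= 3 time columns")
    gene_ids = df.iloc[:, 0].tolist()
    times = np.array([_parse_time_label(c) for c in df.columns[1:]])
    raw = df.iloc[:, 1:]
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy() & ~raw.isna().to_numpy())
    if bad.size:
        r, c = bad[0]
        raise ExpressionLoadError(
            f"non-numeric cell {raw.iat[r, c]!r} at gene {gene_ids[r]!r}, column {raw.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ExpressionLoadError(f"missing value at gene {gene_ids[r]!r}, column {raw.columns[c]!r}")
    values = _convert_to_ln(numeric.to_numpy(dtype=float), scale_tag, gene_ids, times)
    return ExpressionMatrix(gene_ids, times, values, scale_tag)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    """Write the natural-log values as TSV (round-trips with scale_tag='natural_log')."""
    cols = ["gene_id"] + [f"t{t:g}" for t in matrix.times]
    df = pd.DataFrame(matrix.values, columns=cols[1:])
    df.insert(0, "gene_id", matrix.gene_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_annotation(path, matrix: ExpressionMatrix | None = None) -> GeneAnnotation:
    """Read a BED-like annotation (chrom, start, end, gene_id[, strand[, symbol]]).

    Records with start >= end are rejected and reported.  When an expression
    matrix is supplied, annotation rows for genes absent from it are dropped
    with a logged count; zero overlap yields an empty result plus a warning.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 4:
        raise AnnotationError("need >= 4 columns: chrom, start, end, gene_id")
    rec = pd.DataFrame(
        {
            "chrom": df.iloc[:, 0],
            "start": pd.to_numeric(df.iloc[:, 1]).astype(int),
            "end": pd.to_numeric(df.iloc[:, 2]).astype(int),
            "gene_id": df.iloc[:, 3],
        }
    )
    if df.shape[1] >= 5:
        col5 = df.iloc[:, 4].astype(str)
        if col5.isin(["+", "-", "."]).all():
            rec["strand"] = col5
            if df.shape[1] >= 6:
                rec["symbol"] = df.iloc[:, 5]
        else:
            rec["symbol"] = col5
    bad = rec[rec.start >= rec.end]
    if len(bad):
        logger.warning("rejecting %d records with start >= end: %s", len(bad), bad.gene_id.tolist()[:10])
        rec = rec[rec.start < rec.end]
    if matrix is not None:
        keep = rec.gene_id.isin(set(matrix.gene_ids))
        dropped = int((~keep).sum())
        if dropped:
            logger.info("dropping %d annotated genes absent from the expression matrix", dropped)
        rec = rec[keep]
        if not len(rec):
            logger.warning("annotation covers none of the expression matrix's genes")
    return GeneAnnotation(rec.reset_index(drop=True))


def dedupe_probes(matrix: ExpressionMatrix, annotation: GeneAnnotation):
    """Collapse multiple probes of one gene to a single representative row.

    The representative is the probe with the highest temporal mean expression;
    ties are broken by the lexicographically smallest probe id.  Requires a
    ``symbol`` column in the annotation mapping probes to gene symbols;
    without one this is a no-op.  Returns ``(matrix, mapping_table)``.
    """
    if not len(annotation) or "symbol" not in annotation.records.columns:
        return matrix, pd.DataFrame(columns=["probe_id", "symbol", "kept"])
    sym = dict(zip(annotation.records.gene_id, annotation.records.symbol))
    means = matrix.values.mean(axis=1)
    rows = pd.DataFrame(
        {
            "probe_id": matrix.gene_ids,
            "symbol": [sym.get(g) for g in matrix.gene_ids],
            "mean": means,
        }
    )
    keep_mask = np.ones(len(rows), dtype=bool)
    mapping = []
    for symbol, grp in rows[rows.symbol.notna()].groupby("symbol"):
        if len(grp) == 1:
            continue
        best = grp.sort_values(["mean", "probe_id"], ascending=[False, True], kind="mergesort").iloc[0]
        for idx, row in grp.iterrows():
            kept = row.probe_id == best.probe_id
            mapping.append({"probe_id": row.probe_id, "symbol": symbol, "kept": kept})
            if not kept:
                keep_mask[idx] = False
    table = pd.DataFrame(mapping, columns=["probe_id", "symbol", "kept"])
    if keep_mask.all():
        return matrix, table
    ids = [g for g, k in zip(matrix.gene_ids, keep_mask) if k]
    out = ExpressionMatrix(ids, matrix.times.copy(), matrix.values[keep_mask].copy(), "natural_log")
    logger.info("dedupe_probes: %d probes collapsed to %d rows", matrix.n_genes, out.n_genes)
    return out, table
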
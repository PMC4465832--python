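"""Chromosomal barcode genes: maximal same-state runs and their nulls.

A barcode gene is a maximal run of chromosomally consecutive genes sharing
one critical state; its correlation length is the bp span from the start of
the first member to the end of the last.  Runs are closed by an observed
state change; when the input covers a window rather than whole chromosomes,
the final (unclosed) run per chromosome is flagged truncated.  Two nulls
accompany the construction: random-barcode I resamples existing barcodes
across states; random-barcode II rebuilds pseudo-barcodes from random
chromosomal positions with 1-4 neighboring genes, mixing states.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .correlation import correlation_series
from .criticality import CriticalPartition, average_cp, fit_power_law, partition_states
from .fluctuation import compute_rmsf, deab_curve, group_by_key
from .io import ExpressionMatrix, GeneAnnotation

logger = logging.getLogger(__name__)


@dataclass
class Barcode:
    barcode_id: str
    chrom: str
    members: list                 # gene ids in chromosomal order
    state: str                    # 'super' | 'near' | 'sub' | 'mixed' (nulls)
    start: int
    end: int
    truncated: bool = False

    @property
    def correlation_length(self) -> int:
        return self.end - self.start

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class BarcodeSet:
    barcodes: list
    excluded_genes: int = 0       # partitioned genes without usable annotation

    def __len__(self) -> int:
        return len(self.barcodes)

    @property
    def state_counts(self) -> dict:
        out: dict = {}
        for bc in self.barcodes:
            out[bc.state] = out.get(bc.state, 0) + 1
        return out

    def single_gene_fraction(self, state: str) -> float:
        of_state = [bc for bc in self.barcodes if bc.state == state]
        if not of_state:
            return float("nan")
        return sum(1 for bc in of_state if bc.size == 1) / len(of_state)

    def complete(self) -> list:
        return [bc for bc in self.barcodes if not bc.truncated]

    def to_expression_matrix(self, matrix: ExpressionMatrix, aggregate: str = "mean_ln") -> ExpressionMatrix:
        """Barcode-level expression with equal member weighting.

        Default is the arithmetic mean of ln eps (every member gene
        contributes equally, so a domain is represented by its typical
        member); ``aggregate='mean_linear'`` switches to the mean of linear
        eps, which lets the highest-expressed member dominate the unit.
        """
        pos = {g: i for i, g in enumerate(matrix.gene_ids)}
        vals = np.empty((len(self.barcodes), matrix.n_times))
        for i, bc in enumerate(self.barcodes):
            rows = np.array([pos[g] for g in bc.members])
            if aggregate == "mean_linear":
                vals[i] = np.log(np.exp(matrix.values[rows]).mean(axis=0))
            elif aggregate == "mean_ln":
                vals[i] = matrix.values[rows].mean(axis=0)
            else:
                raise ValueError(f"unknown aggregate {aggregate!r}")
        ids = [bc.barcode_id for bc in self.barcodes]
        return ExpressionMatrix(ids, matrix.times.copy(), vals, "natural_log")


def build_barcodes(
    partition: CriticalPartition,
    annotation: GeneAnnotation,
    windowed: bool = False,
) -> BarcodeSet:
    """Maximal same-state runs of consecutive genes per chromosome.

    Genes are ordered by (chrom, start, end, gene_id).  Partitioned genes
    lacking annotation are excluded with a logged count.  With
    ``windowed=True`` the final run on each chromosome is flagged truncated
    (it may continue past the window); whole-chromosome runs are never
    truncated.
    """
    rec = annotation.sorted()
    known = rec[rec.gene_id.isin(partition.states.index)]
    excluded = len(partition.states) - len(known)
    if excluded:
        logger.info("build_barcodes: %d partitioned genes lack annotation and are excluded", excluded)
    barcodes = []
    for chrom, chrom_rec in known.groupby("chrom", sort=True):
        run_rows = []
        run_state = None
        rows = list(chrom_rec.itertuples())
        for row in rows:
            state = partition.states[row.gene_id]
            if run_state is None or state == run_state:
                run_rows.append(row)
                run_state = state
            else:
                barcodes.append(_close_run(chrom, run_rows, run_state, len(barcodes)))
                run_rows, run_state = [row], state
        if run_rows:
            bc = _close_run(chrom, run_rows, run_state, len(barcodes))
            bc.truncated = bool(windowed)
            barcodes.append(bc)
    return BarcodeSet(barcodes, excluded)


def _close_run(chrom: str, rows: list, state: str, idx: int) -> Barcode:
    return Barcode(
        barcode_id=f"bc{idx:06d}",
        chrom=chrom,
        members=[r.gene_id for r in rows],
        state=state,
        start=int(rows[0].start),
        end=int(rows[-1].end),
    )


def barcode_length_histogram(bset: BarcodeSet, bin_width: float = 0.1, include_truncated: bool = False) -> pd.DataFrame:
    """Per-state histogram of log10 correlation length (0.1-decade bins).

    Returns a tidy frame with columns state, log10_bp_lo, log10_bp_hi, count.
    """
    barcodes = bset.barcodes if include_truncated else bset.complete()
    if not barcodes:
        raise ValueError("empty barcode set")
    rows = []
    for state in sorted({bc.state for bc in barcodes}):
        lengths = np.array([bc.correlation_length for bc in barcodes if bc.state == state], dtype=float)
        logs = np.log10(lengths)
        lo = np.floor(logs.min() / bin_width) * bin_width
        hi = np.ceil(logs.max() / bin_width) * bin_width + bin_width / 2
        edges = np.arange(lo, hi, bin_width)
        if edges.size < 2:
            edges = np.array([lo, lo + bin_width])
        counts, edges = np.histogram(logs, bins=edges)
        for c, elo, ehi in zip(counts, edges[:-1], edges[1:]):
            if c:
                rows.append({"state": state, "log10_bp_lo": float(elo), "log10_bp_hi": float(ehi), "count": int(c)})
    return pd.DataFrame(rows)


def random_barcode_I(
    bset: BarcodeSet,
    matrix: ExpressionMatrix,
    n_select: int = 200,
    repeats: int = 100,
    seed: int = 0,
    series_id: str = "P(t0;tj)",
) -> dict:
    """Null correlation series from randomly selected barcodes across states.

    Per repeat, ``n_select`` barcodes are sampled without replacement from
    the whole set (states mixed) and the temporal correlation series is
    computed on their barcode-level expression; the repeat average (and SD)
    is returned.  Selecting the whole set reproduces the pooled series.
    """
    if len(bset) < n_select:
        raise ValueError(f"n_select = {n_select} exceeds the barcode count {len(bset)}")
    bc_matrix = bset.to_expression_matrix(matrix)
    rng = np.random.default_rng(seed)
    vals = []
    times = None
    for _ in range(repeats):
        rows = np.sort(rng.choice(len(bset), size=n_select, replace=False))
        ids = [bc_matrix.gene_ids[i] for i in rows]
        series = correlation_series(bc_matrix, ids, series_id)
        times = series.times
        vals.append(series.values)
    vals = np.array(vals)
    return {
        "series_id": series_id,
        "times": times,
        "mean": vals.mean(axis=0),
        "sd": vals.std(axis=0, ddof=0),
        "n_select": n_select,
        "repeats": repeats,
        "seed": seed,
    }


def random_barcode_II(
    partition: CriticalPartition,
    annotation: GeneAnnotation,
    n_barcodes: int = 3130,
    seed: int = 0,
    extension: tuple = (1, 4),
) -> BarcodeSet:
    """State-mixing null: pseudo-barcodes built from random positions.

    Repeatedly picks a random unused gene position on a chromosome and
    joins it with u ~ Uniform{extension} consecutive unused neighboring
    genes to its right (stopping early at used genes or the chromosome
    end), ignoring state labels, until ``n_barcodes`` pseudo-barcodes exist
    or genes run out.  The default extension (1, 4) attaches 1-4 neighbors
    to every selected gene, so each pseudo-barcode genuinely mixes
    positions; ``extension=(0, 0)`` degenerates to singletons.  A
    pseudo-barcode's state is 'mixed' unless its members happen to share
    one state.
    """
    rec = annotation.sorted()
    known = rec[rec.gene_id.isin(partition.states.index)].reset_index(drop=True)
    rng = np.random.default_rng(seed)
    n = len(known)
    used = np.zeros(n, dtype=bool)
    chrom_arr = known.chrom.to_numpy()
    order = rng.permutation(n)
    barcodes = []
    for start in order:
        if len(barcodes) >= n_barcodes:
            break
        if used[start]:
            continue
        u = 1 + int(rng.integers(extension[0], extension[1] + 1))
        rows = []
        for i in range(start, min(start + u, n)):
            if used[i] or chrom_arr[i] != chrom_arr[start]:
                break
            rows.append(i)
        for i in rows:
            used[i] = True
        sub = known.iloc[rows]
        states = {partition.states[g] for g in sub.gene_id}
        barcodes.append(
            Barcode(
                barcode_id=f"rb{len(barcodes):06d}",
                chrom=str(chrom_arr[start]),
                members=sub.gene_id.tolist(),
                state=states.pop() if len(states) == 1 else "mixed",
                start=int(sub.start.iloc[0]),
                end=int(sub.end.iloc[-1]),
            )
        )
    if len(barcodes) < n_barcodes:
        logger.info("random_barcode_II: produced %d of %d requested pseudo-barcodes", len(barcodes), n_barcodes)
    return BarcodeSet(barcodes)


def barcode_pipeline(
    bset: BarcodeSet,
    matrix: ExpressionMatrix,
    group_size: int = 182,
    thresholds: tuple = (0.08, 0.16),
    cp_pairs=((10, 15), (15, 20), (20, 30)),
    deab_time: float | None = None,
    powerlaw_nrmsf_max: float = 1.0,
) -> dict:
    """Re-run the SOC pipeline treating each barcode as a unit.

    Builds the barcode-level expression matrix, recomputes rmsf / nrmsf,
    the nrmsf grouping and DEAB curve, the power-law fit (restricted to
    groups with <nrmsf> <= ``powerlaw_nrmsf_max``), the sandpile CP averaged
    over ``cp_pairs`` and the state partition.  A set of singleton barcodes
    reproduces the gene-level results exactly.
    """
    bc_matrix = bset.to_expression_matrix(matrix)
    fluct = compute_rmsf(bc_matrix)
    grouping, traj = group_by_key(fluct, bc_matrix, key="nrmsf_desc", n=group_size)
    t0 = deab_time if deab_time is not None else float(bc_matrix.times[0])
    deab = deab_curve(traj, bc_matrix, t0)
    keep = traj.cm_nrmsf[np.argsort(-traj.cm_nrmsf, kind="stable")] <= powerlaw_nrmsf_max
    pl = fit_power_law(np.exp(deab[keep, 0]), 1.0 - np.exp(deab[keep, 1]))
    cp = average_cp(bc_matrix, cp_pairs, n=group_size, fluct=fluct)
    part = partition_states(fluct, thresholds)
    return {
        "matrix": bc_matrix,
        "fluct": fluct,
        "grouping": grouping,
        "trajectory": traj,
        "deab": deab,
        "power_law": pl,
        "cp": cp,
        "partition": part,
    }
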
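"""Temporal fluctuation statistics and mean-field groupings.

The order parameter of the whole analysis is the per-gene root-mean-square
fluctuation of linear-scale expression over the time course,

    rmsf_i = sqrt( (1/(T+1)) * sum_j (eps_i(t_j) - mean_j eps_i)^2 ),

normalized genome-wide to nrmsf_i = rmsf_i / max_i rmsf_i in [0, 1].
Genes sorted by nrmsf (or by expression change between two times) are cut
into k equal groups of n genes; the per-group, per-time centers of mass form
the mean-field trajectory from which DEAB (dynamic emergent averaging
behavior) curves {ln<eps(t_j)>, ln(1 - <nrmsf>)} are built.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class FluctuationTable:
    """Per-gene rmsf / nrmsf plus the genome-wide normalization constant."""

    table: pd.DataFrame  # index: gene_id; columns: rmsf, nrmsf, mean_expr
    max_rmsf: float

    @property
    def rmsf(self) -> pd.Series:
        return self.table["rmsf"]

    @property
    def nrmsf(self) -> pd.Series:
        return self.table["nrmsf"]


@dataclass
class Grouping:
    """Equal-size gene groups ordered by a sort key (group 1 = highest key)."""

    key: str  # 'nrmsf_desc' or 'expression_change'
    n: int
    k: int
    assignment: pd.Series  # gene_id -> group index 1..k (grouped genes only)
    dropped: list = field(default_factory=list)  # remainder genes, lowest-key tail

    def members(self, group: int) -> list:
        return self.assignment.index[self.assignment == group].tolist()


@dataclass
class GroupTrajectory:
    """Per-group, per-time center-of-mass coordinates (the mean field).

    ``mean_ln`` holds <ln eps> (the CM on log scale), ``ln_mean`` holds
    ln<eps> (log of the linear-scale group average; the default DEAB x
    coordinate), ``cm_nrmsf`` the group-average nrmsf, and ``cm_change``
    (change-grouping only) the group-average ln(eps(t_b)/eps(t_a)).
    """

    group_index: np.ndarray          # (k,)
    mean_ln: np.ndarray              # (k, T+1)  <ln eps>
    ln_mean: np.ndarray              # (k, T+1)  ln <eps>
    cm_nrmsf: np.ndarray             # (k,)      <nrmsf>
    cm_change: np.ndarray | None = None  # (k,) for change grouping


def compute_rmsf(matrix: ExpressionMatrix, rmsf_scale: str = "linear") -> FluctuationTable:
    """Per-gene rmsf with the population (1/(T+1)) denominator, and nrmsf.

    ``rmsf_scale='linear'`` (default) evaluates the fluctuation on linear
    expression eps = exp(x); ``'ln'`` evaluates it on the stored log values,
    for sensitivity checks.
    """
    if matrix.n_times < 2:
        raise ValueError("rmsf needs at least two time points")
    eps = matrix.linear() if rmsf_scale == "linear" else matrix.values
    if rmsf_scale not in ("linear", "ln"):
        raise ValueError(f"unknown rmsf_scale {rmsf_scale!r}")
    rmsf = eps.std(axis=1, ddof=0)
    max_rmsf = float(rmsf.max())
    nrmsf = rmsf / max_rmsf if max_rmsf > 0 else np.zeros_like(rmsf)
    table = pd.DataFrame(
        {"rmsf": rmsf, "nrmsf": nrmsf, "mean_expr": matrix.values.mean(axis=1)},
        index=pd.Index(matrix.gene_ids, name="gene_id"),
    )
    return FluctuationTable(table, max_rmsf)


def _sort_order(values: pd.Series) -> pd.Index:
    """Descending by value, ties broken by gene id (stable, reproducible)."""
    df = pd.DataFrame({"v": values})
    df = df.sort_index(kind="mergesort").sort_values("v", ascending=False, kind="mergesort")
    return df.index


def expression_change(matrix: ExpressionMatrix, t_a: float, t_b: float) -> pd.Series:
    """Per-gene log fold change ln(eps(t_b)/eps(t_a)) = x(t_b) - x(t_a)."""
    ja, jb = matrix.index_of_time(t_a), matrix.index_of_time(t_b)
    d = matrix.values[:, jb] - matrix.values[:, ja]
    return pd.Series(d, index=pd.Index(matrix.gene_ids, name="gene_id"))


def group_by_key(
    fluct: FluctuationTable,
    matrix: ExpressionMatrix,
    key: str = "nrmsf_desc",
    n: int = 440,
    time_pair: tuple | None = None,
):
    """Sort genes by the key and cut into k = floor(N/n) equal groups.

    Group 1 holds the n highest-key genes; the N mod n remainder genes are
    dropped from the lowest-key tail and logged.  Returns
    ``(Grouping, GroupTrajectory)``.
    """
    if n < 2:
        raise ValueError("group size n must be >= 2")
    N = matrix.n_genes
    if n > N:
        raise ValueError(f"group size {n} exceeds N = {N}")
    if key == "nrmsf_desc":
        sort_vals = fluct.nrmsf
    elif key == "expression_change":
        if time_pair is None:
            raise ValueError("expression_change grouping needs a (t_a, t_b) time pair")
        sort_vals = expression_change(matrix, *time_pair)
    else:
        raise ValueError(f"unknown grouping key {key!r}")
    order = _sort_order(sort_vals)
    k = N // n
    grouped = order[: k * n]
    dropped = order[k * n :].tolist()
    if dropped:
        logger.info("group_by_key: dropped %d remainder genes from the low-key tail", len(dropped))
    assignment = pd.Series(np.repeat(np.arange(1, k + 1), n), index=grouped, name="group")

    pos = {g: i for i, g in enumerate(matrix.gene_ids)}
    rows = np.array([pos[g] for g in grouped])
    x = matrix.values[rows].reshape(k, n, matrix.n_times)
    eps = np.exp(x)
    mean_ln = x.mean(axis=1)
    ln_mean = np.log(eps.mean(axis=1))
    nr = fluct.nrmsf.loc[grouped].to_numpy().reshape(k, n).mean(axis=1)
    cm_change = None
    if key == "expression_change":
        cm_change = sort_vals.loc[grouped].to_numpy().reshape(k, n).mean(axis=1)
    traj = GroupTrajectory(np.arange(1, k + 1), mean_ln, ln_mean, nr, cm_change)
    return Grouping(key, n, k, assignment, dropped), traj


def deab_curve(traj: GroupTrajectory, matrix: ExpressionMatrix, t_j: float, average: str = "ln_mean") -> np.ndarray:
    """DEAB points (ln<eps(t_j)>, ln(1 - <nrmsf>)), one per group.

    Ordered by descending <nrmsf> (group order).  ``average='mean_ln'``
    switches the x coordinate to <ln eps>.  A group with <nrmsf> = 1 would
    make ln(1 - .) singular and is excluded with a warning.
    """
    j = matrix.index_of_time(t_j)
    xs = traj.ln_mean[:, j] if average == "ln_mean" else traj.mean_ln[:, j]
    keep = traj.cm_nrmsf < 1.0
    if not keep.all():
        logger.warning("deab_curve: excluding %d group(s) with <nrmsf> >= 1", int((~keep).sum()))
    order = np.argsort(-traj.cm_nrmsf[keep], kind="stable")
    pts = np.column_stack([xs[keep], np.log(1.0 - traj.cm_nrmsf[keep])])
    return pts[order]


def group_size_convergence(
    fluct: FluctuationTable,
    matrix: ExpressionMatrix,
    t_j: float,
    n_max: int,
    start_rank: int = 0,
) -> pd.DataFrame:
    """Convergence of first-n ensemble coordinates: D(n; n-1) for n = 2..n_max.

    The ensemble is built by walking the nrmsf-descending gene order starting
    at ``start_rank``; its coordinates are (x, y) = (<nrmsf>, ln<eps(t_j)>)
    and D(n; n-1) = (x_n - x_{n-1}) + (y_n - y_{n-1}).  By the law of large
    numbers |D| shrinks toward zero as n grows.
    """
    order = _sort_order(fluct.nrmsf)[start_rank:]
    if n_max > len(order):
        logger.warning("group_size_convergence: n_max %d clipped to %d", n_max, len(order))
        n_max = len(order)
    pos = {g: i for i, g in enumerate(matrix.gene_ids)}
    rows = np.array([pos[g] for g in order[:n_max]])
    j = matrix.index_of_time(t_j)
    eps = np.exp(matrix.values[rows, j])
    nr = fluct.nrmsf.loc[order[:n_max]].to_numpy()
    ns = np.arange(1, n_max + 1)
    x = np.cumsum(nr) / ns
    y = np.log(np.cumsum(eps) / ns)
    d = (x[1:] - x[:-1]) + (y[1:] - y[:-1])
    return pd.DataFrame({"n": ns[1:], "D": d})
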
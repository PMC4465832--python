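"""Scaled correlation dynamics and the center-of-mass correlation algebra.

All correlations here are *between profiles*: genes are the statistical
units and two sample profiles (time points, or change vectors between time
points) are the variables.  The scaled correlation generalizes the Pearson
product-moment coefficient by the choice of reference vector: the zero
vector (cosine-style), each vector's own group center of mass (ordinary
Pearson), or the whole-expression center of mass at that time.

The center-of-mass (CM) approximation expresses the correlation between
expression and expression change through the motion of the ensemble CM:

    P(t_j; t_{j+1}-t_j)  ~=  alpha * lambda_j * (<x(t_j)> - <x(t_{j+1})>),

with lambda_j = N(t_j)/N(t_{j+1}-t_j), the ratio of the deviation norms of
the expression vector and the change vector, and alpha a single constant
fitted by least squares over the time course.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .criticality import CriticalPartition
from .fluctuation import Grouping, GroupTrajectory
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

SCALING_MODES = ("none", "cm_group", "cm_whole")
SERIES_IDS = ("P(t0;tj)", "P(tj;tj+1)", "P(tj;tj+1-tj)", "P(t1-t0;tj+1-tj)")


class ScalingMode:
    """Reference-vector options for the scaled correlation."""

    NONE = "none"
    CM_GROUP = "cm_group"
    CM_WHOLE = "cm_whole"


@dataclass
class CorrelationSeries:
    series_id: str
    times: np.ndarray     # time (minutes) indexing each value
    values: np.ndarray    # correlation per index; NaN where undefined


@dataclass
class CMApproximation:
    """Exact vs CM-approximated P(t_j; t_{j+1}-t_j) series."""

    alpha: float
    lambda_j: np.ndarray   # N(t_j)/N(t_{j+1}-t_j), per change step
    gamma_j: np.ndarray    # N(t_{j+1})/N(t_j)
    beta_j: np.ndarray     # alpha (2 N(t_1) - N(t_0)) / (N(t_1-t_0) N(t_{j+1}-t_j))
    cm: np.ndarray         # <x(t_j)>, per time point
    norms: np.ndarray      # N(t_j), per time point
    change_norms: np.ndarray  # N(t_{j+1}-t_j), per change step
    exact: np.ndarray      # exact Pearson P(t_j; t_{j+1}-t_j)
    approx: np.ndarray     # alpha * lambda_j * (<x(t_j)> - <x(t_{j+1})>)
    fit_distance: float    # Euclidean distance between exact and approx


@dataclass
class FocalPoint:
    found: bool
    nrmsf_fp: float | None
    group: int | None
    spread_profile: np.ndarray  # across-time dispersion per group
    inverted: bool | None       # whether the time ordering of curves flips across the FP
    curves: np.ndarray          # (n_times, k) cm_whole-scaled correlation curves


@dataclass
class EnsembleSizeScan:
    sizes: np.ndarray
    repeats: int
    seed: int
    delta_mean: np.ndarray  # (n_sizes, T) mean over repeats of P_m - P_full, series P(tj;tj+1-tj)
    delta_sd: np.ndarray
    d0_mean: np.ndarray     # (n_sizes, T) mean of P(t1-t0;tj+1-tj) of the sample
    d0_sd: np.ndarray
    scaling: dict = field(default_factory=dict)  # per statistic: exponent, prefactor


@dataclass
class AttractorField:
    t_a: float
    t_b: float
    x: np.ndarray       # x_i(t_a)
    y: np.ndarray       # x_i(t_b)
    dx: np.ndarray      # x_i(t_b) - x_i(t_a)
    dy: np.ndarray | None  # x_i(t_next) - x_i(t_b), None when t_b is last
    r: float            # between-profiles Pearson of the two columns

    def standardized(self):
        """(x*, y*) standardized coordinates; the manifold is y* = r x*."""
        xs = (self.x - self.x.mean()) / self.x.std(ddof=0)
        ys = (self.y - self.y.mean()) / self.y.std(ddof=0)
        return xs, ys


def scaled_correlation(x1, xk, mode: str = "cm_group", r1: float | None = None, rk: float | None = None) -> float:
    """Scaled correlation of two equal-length expression vectors.

    ``mode='none'`` uses the zero reference (cosine similarity),
    ``'cm_group'`` subtracts each vector's own mean (ordinary Pearson), and
    ``'cm_whole'`` subtracts the externally supplied whole-expression means
    ``r1``/``rk``.  A zero denominator returns NaN.
    """
    a = np.asarray(x1, dtype=float)
    b = np.asarray(xk, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("vectors must have equal length >= 2")
    if mode == "none":
        da, db = a, b
    elif mode == "cm_group":
        da, db = a - a.mean(), b - b.mean()
    elif mode == "cm_whole":
        if r1 is None or rk is None:
            raise ValueError("cm_whole scaling needs the whole-expression means r1 and rk")
        da, db = a - r1, b - rk
    else:
        raise ValueError(f"unknown scaling mode {mode!r}")
    denom = np.sqrt((da**2).sum() * (db**2).sum())
    if denom == 0:
        return float("nan")
    return float((da * db).sum() / denom)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    da, db = a - a.mean(), b - b.mean()
    denom = np.sqrt((da**2).sum() * (db**2).sum())
    return float((da * db).sum() / denom) if denom > 0 else float("nan")


def correlation_series(matrix: ExpressionMatrix, genes, series_id: str) -> CorrelationSeries:
    """Temporal between-profiles correlation series for a gene subset.

    Supported ids: ``P(t0;tj)`` (j = 0..T), ``P(tj;tj+1)``,
    ``P(tj;tj+1-tj)`` and ``P(t1-t0;tj+1-tj)`` (j = 0..T-1); change vectors
    are x(t_{j+1}) - x(t_j) on the natural-log scale.  Indices at which a
    vector is constant are NaN.
    """
    if series_id not in SERIES_IDS:
        raise ValueError(f"unknown series {series_id!r}; expected one of {SERIES_IDS}")
    sub = matrix.subset(genes) if genes is not None else matrix
    if sub.n_genes < 2:
        raise ValueError("correlation series needs >= 2 genes")
    x = sub.values
    T1 = sub.n_times
    if series_id == "P(t0;tj)":
        vals = np.array([_pearson(x[:, 0], x[:, j]) for j in range(T1)])
        return CorrelationSeries(series_id, sub.times.copy(), vals)
    d = np.diff(x, axis=1)  # (N, T)
    if series_id == "P(tj;tj+1)":
        vals = np.array([_pearson(x[:, j], x[:, j + 1]) for j in range(T1 - 1)])
    elif series_id == "P(tj;tj+1-tj)":
        vals = np.array([_pearson(x[:, j], d[:, j]) for j in range(T1 - 1)])
    else:  # P(t1-t0;tj+1-tj)
        vals = np.array([_pearson(d[:, 0], d[:, j]) for j in range(T1 - 1)])
    return CorrelationSeries(series_id, sub.times[:-1].copy(), vals)


def cm_approximation(matrix: ExpressionMatrix, genes) -> CMApproximation:
    """Fit the CM correlation algebra on a coherent gene ensemble.

    Computes the deviation norms N(t_j) and N(t_{j+1}-t_j), the ratios
    lambda_j, gamma_j, beta_j, the exact Pearson series P(t_j; t_{j+1}-t_j)
    and its CM approximation alpha * lambda_j * (<x(t_j)> - <x(t_{j+1})>),
    with alpha minimizing the Euclidean distance between the two series.
    """
    sub = matrix.subset(genes) if genes is not None else matrix
    if sub.n_genes < 50:
        logger.warning("cm_approximation: ensemble of %d genes is below the n = 50 coherence scale", sub.n_genes)
    x = sub.values
    cm = x.mean(axis=0)
    norms = np.sqrt(((x - cm) ** 2).sum(axis=0))
    d = np.diff(x, axis=1)
    dcm = d.mean(axis=0)
    change_norms = np.sqrt(((d - dcm) ** 2).sum(axis=0))
    if np.any(norms == 0) or np.any(change_norms == 0):
        raise ValueError("zero deviation norm: CM algebra undefined")
    lam = norms[:-1] / change_norms
    gam = norms[1:] / norms[:-1]
    exact = np.array([_pearson(x[:, j], d[:, j]) for j in range(d.shape[1])])
    base = lam * (cm[:-1] - cm[1:])
    denom = (base**2).sum()
    alpha = float((base * exact).sum() / denom) if denom > 0 else float("nan")
    approx = alpha * base
    beta_j = alpha * (2.0 * norms[1] - norms[0]) / (change_norms[0] * change_norms)
    return CMApproximation(
        alpha=alpha,
        lambda_j=lam,
        gamma_j=gam,
        beta_j=beta_j,
        cm=cm,
        norms=norms,
        change_norms=change_norms,
        exact=exact,
        approx=approx,
        fit_distance=float(np.linalg.norm(exact - approx)),
    )


def detect_focal_point(
    matrix: ExpressionMatrix,
    grouping: Grouping,
    traj: GroupTrajectory,
    times,
    flat_tol: float = 0.05,
) -> FocalPoint:
    """Locate the focal point of whole-CM-scaled group correlation curves.

    For each requested time, the curve over groups is the scaled correlation
    (cm_whole reference) between group 1's expression vector and each
    group's.  The focal point is the group minimizing the across-time
    dispersion of the curves; a dispersion profile whose range is below
    ``flat_tol`` x its median is reported as no-FP (parallel curves).
    Also reports whether the time ordering of the curves inverts across the FP.
    """
    times = list(times)
    if len(times) < 3:
        raise ValueError("focal-point detection needs >= 3 time points")
    k = grouping.k
    pos = {g: i for i, g in enumerate(matrix.gene_ids)}
    member_rows = [np.array([pos[g] for g in grouping.members(gi)]) for gi in range(1, k + 1)]
    curves = np.empty((len(times), k))
    for ti, t in enumerate(times):
        j = matrix.index_of_time(t)
        col = matrix.values[:, j]
        whole_cm = float(col.mean())
        x1 = col[member_rows[0]]
        for gi in range(k):
            curves[ti, gi] = scaled_correlation(col[member_rows[gi]], x1, "cm_whole", whole_cm, whole_cm)
    spread = curves.std(axis=0, ddof=0)
    med = float(np.median(spread))
    if med == 0 or (spread.max() - spread.min()) < flat_tol * med:
        return FocalPoint(False, None, None, spread, None, curves)
    g_fp = int(np.argmin(spread))
    nrmsf_fp = float(traj.cm_nrmsf[g_fp])
    inverted = None
    if 0 < g_fp < k - 1:
        before = curves[:, :g_fp].mean(axis=1)
        after = curves[:, g_fp + 1 :].mean(axis=1)
        rb = np.argsort(np.argsort(before))
        ra = np.argsort(np.argsort(after))
        inverted = bool(_pearson(rb.astype(float), ra.astype(float)) < 0)
    return FocalPoint(True, nrmsf_fp, g_fp + 1, spread, inverted, curves)


def _sample_rows(rng: np.random.Generator, n: int, m: int) -> np.ndarray:
    """Sorted sample without replacement (canonical: m = n gives the full set)."""
    return np.sort(rng.choice(n, size=m, replace=False))


def minimal_ensemble_scan(
    matrix: ExpressionMatrix,
    genes,
    sizes,
    repeats: int = 400,
    seed: int = 0,
    scaling_js=(1, 2, 3),
) -> EnsembleSizeScan:
    """Random-subsample scan of the coherence of the correlation series.

    For each ensemble size m (sampled without replacement, ``repeats``
    times) records (a) the deviation of P(t_j; t_{j+1}-t_j) from the full
    ensemble's series and (b) P(t_1-t_0; t_{j+1}-t_j) of the sample.  The
    SD over repeats at the time indices ``scaling_js`` is regressed as
    log SD ~ log m to report an empirical scaling exponent per statistic.
    """
    sub = matrix.subset(genes) if genes is not None else matrix
    sizes = np.asarray(sorted(sizes), dtype=int)
    if sizes.max() > sub.n_genes:
        raise ValueError("max ensemble size exceeds the subset size")
    rng = np.random.default_rng(seed)
    x = sub.values
    d = np.diff(x, axis=1)
    T = d.shape[1]
    full = np.array([_pearson(x[:, j], d[:, j]) for j in range(T)])
    delta_mean = np.empty((sizes.size, T))
    delta_sd = np.empty((sizes.size, T))
    d0_mean = np.empty((sizes.size, T))
    d0_sd = np.empty((sizes.size, T))
    for si, m in enumerate(sizes):
        dvals = np.empty((repeats, T))
        d0vals = np.empty((repeats, T))
        for rep in range(repeats):
            rows = _sample_rows(rng, sub.n_genes, int(m))
            xs, ds = x[rows], d[rows]
            dvals[rep] = [_pearson(xs[:, j], ds[:, j]) - full[j] for j in range(T)]
            d0vals[rep] = [_pearson(ds[:, 0], ds[:, j]) for j in range(T)]
        delta_mean[si], delta_sd[si] = dvals.mean(axis=0), dvals.std(axis=0, ddof=0)
        d0_mean[si], d0_sd[si] = d0vals.mean(axis=0), d0vals.std(axis=0, ddof=0)
    scaling = {}
    js = [j for j in scaling_js if j < T]
    for name, sd in (("delta_P", delta_sd), ("P_d0", d0_sd)):
        pooled = sd[:, js].mean(axis=1)
        ok = pooled > 0
        if ok.sum() >= 2:
            slope, intercept = np.polyfit(np.log(sizes[ok]), np.log(pooled[ok]), 1)
            scaling[name] = {"exponent": float(-slope), "prefactor": float(np.exp(intercept))}
        else:
            scaling[name] = {"exponent": float("nan"), "prefactor": float("nan")}
    return EnsembleSizeScan(sizes, repeats, seed, delta_mean, delta_sd, d0_mean, d0_sd, scaling)


def between_state_sampling(
    matrix: ExpressionMatrix,
    partition: CriticalPartition,
    state_a: str = "super",
    state_b: str = "sub",
    m: int = 100,
    repeats: int = 200,
    seed: int = 0,
    convergence_sizes=None,
) -> dict:
    """Correlation of randomly sampled center-of-mass dynamics between states.

    Per repeat, m genes are sampled from each state; the per-state CM change
    series <x(t_{j+1})> - <x(t_j)> (and CM expression series) are correlated
    across states over time.  Identical states give +1; anti-phase
    oscillating states converge to strongly negative values.  When
    ``convergence_sizes`` is given, also reports the Euclidean distance
    between the standardized correlation-contribution curves at consecutive
    sizes m and m+1 (repeat-averaged), which shrinks as coherence emerges.
    """
    genes_a = partition.genes(state_a)
    genes_b = partition.genes(state_b)
    if m > len(genes_a) or m > len(genes_b):
        raise ValueError(f"m = {m} exceeds a state size ({len(genes_a)}, {len(genes_b)})")
    pos = {g: i for i, g in enumerate(matrix.gene_ids)}
    rows_a = np.array([pos[g] for g in genes_a])
    rows_b = np.array([pos[g] for g in genes_b])
    rng = np.random.default_rng(seed)

    def _one(m_use):
        change_r = np.empty(repeats)
        expr_r = np.empty(repeats)
        contrib = np.zeros(matrix.n_times - 1)
        for rep in range(repeats):
            sa = rows_a[_sample_rows(rng, rows_a.size, m_use)]
            sb = rows_b[_sample_rows(rng, rows_b.size, m_use)]
            cma = matrix.values[sa].mean(axis=0)
            cmb = matrix.values[sb].mean(axis=0)
            da, db = np.diff(cma), np.diff(cmb)
            change_r[rep] = _pearson(da, db)
            expr_r[rep] = _pearson(cma, cmb)
            za = (da - da.mean()) / da.std(ddof=0) if da.std(ddof=0) > 0 else da * 0
            zb = (db - db.mean()) / db.std(ddof=0) if db.std(ddof=0) > 0 else db * 0
            contrib += za * zb / da.size
        return change_r, expr_r, contrib / repeats

    change_r, expr_r, _ = _one(m)
    out = {
        "cm_change_corr_mean": float(np.nanmean(change_r)),
        "cm_change_corr_sd": float(np.nanstd(change_r)),
        "cm_expr_corr_mean": float(np.nanmean(expr_r)),
        "cm_expr_corr_sd": float(np.nanstd(expr_r)),
        "m": m,
        "repeats": repeats,
        "seed": seed,
    }
    if convergence_sizes is not None:
        sizes = sorted(convergence_sizes)
        curves = {ms: _one(ms)[2] for ms in set(sizes) | {ms + 1 for ms in sizes}}
        out["convergence"] = pd.DataFrame(
            {"m": sizes, "distance": [float(np.linalg.norm(curves[ms] - curves[ms + 1])) for ms in sizes]}
        )
    return out


def attractor_field(matrix: ExpressionMatrix, t_a: float, t_b: float) -> AttractorField:
    """Whole-expression flow between two time points.

    Points are (x_i(t_a), x_i(t_b)); vectors are the subsequent displacement
    (dx toward t_b, dy toward the next grid time after t_b, when one
    exists).  The summary r is the between-profiles Pearson correlation of
    the two columns; in standardized coordinates the attracting manifold is
    the line y = r x.
    """
    ja, jb = matrix.index_of_time(t_a), matrix.index_of_time(t_b)
    x = matrix.values[:, ja]
    y = matrix.values[:, jb]
    dx = y - x
    dy = matrix.values[:, jb + 1] - y if jb + 1 < matrix.n_times else None
    r = 1.0 if ja == jb else _pearson(x, y)
    return AttractorField(t_a, t_b, x, y, dx, dy, float(r))
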
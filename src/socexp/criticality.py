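"""Critical-point detection, modality classification and the power law.

The sandpile test regroups genes by their expression change between two
times; in the plane of group-average change (x) versus group-average log
expression (y) a singular apex near x = 0 marks the critical point (CP).
Around the CP the expression distribution switches from unimodal (high
nrmsf) through a flattened profile to bimodal (low nrmsf), quantified by
Sarle's finite-sample bimodality coefficient

    b = (g1^2 + 1) / (g2 + 3 (n-1)^2 / ((n-2)(n-3))),

with sample skewness g1 and sample excess kurtosis g2; b > 5/9 indicates
bi-/multimodality.  The mean-field coupling between group-average
expression and fluctuation follows a power law 1 - <nrmsf> = alpha <eps>^-beta.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal, stats

from .fluctuation import FluctuationTable, GroupTrajectory, compute_rmsf, group_by_key
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

BIMODAL_THRESHOLD = 5.0 / 9.0
FLATTENED_BAND = (0.45, 5.0 / 9.0)  # declared convention; the flattened exemplar is b = 0.49


@dataclass
class BimodalityReport:
    b: float
    n: int
    skewness: float
    excess_kurtosis: float
    modality: str  # 'unimodal' | 'flattened' | 'bimodal'


@dataclass
class CriticalPoint:
    ln_eps: float
    nrmsf: float
    group: int  # 1-based group index in the change grouping
    cm_change: float


@dataclass
class SandpileProfile:
    """Change-grouped mean-field profile with the detected critical point."""

    cm_change: np.ndarray      # per group, <ln(eps(t_b)/eps(t_a))>
    cm_expr: np.ndarray        # per group, <ln eps(t_a)>
    cm_nrmsf: np.ndarray       # per group, <nrmsf>
    cp: CriticalPoint | None
    singularity_score: float   # prominence of the apex; 0 when no transition
    singularity_ratio: float = 0.0  # prominence / profile relief inside the window

    @property
    def transition_detected(self) -> bool:
        return self.cp is not None

    def significant(self, min_ratio: float = 0.5) -> bool:
        """Whether the apex accounts for at least ``min_ratio`` of the
        profile's relief — a scale-free transition flag."""
        return self.cp is not None and self.singularity_ratio >= min_ratio


@dataclass
class RegulatoryDensity:
    """Normalized 2-D histogram over (x = change, y = log expression)."""

    density: np.ndarray        # (nx, ny), sums to 1
    x_edges: np.ndarray
    y_edges: np.ndarray
    modes: list = field(default_factory=list)  # dicts with x, y, density, label

    @property
    def hes(self):
        named = [m for m in self.modes if m.get("label") == "HES"]
        return named[0] if named else None

    @property
    def les(self):
        named = [m for m in self.modes if m.get("label") == "LES"]
        return named[0] if named else None


@dataclass
class CriticalPartition:
    """Per-gene critical-state labels from nrmsf thresholds."""

    states: pd.Series              # gene_id -> 'super' | 'near' | 'sub'
    thresholds: tuple = (0.08, 0.16)

    @property
    def counts(self) -> dict:
        c = self.states.value_counts()
        return {s: int(c.get(s, 0)) for s in ("super", "near", "sub")}

    def genes(self, state: str) -> list:
        return self.states.index[self.states == state].tolist()


@dataclass
class PowerLawFit:
    alpha: float
    beta: float
    r2: float
    p_value: float
    beta_stderr: float
    beta_ci: tuple  # 95% two-sided on beta
    n_points: int


def sarle_b(sample) -> BimodalityReport:
    """Sarle's finite-sample bimodality coefficient with modality class.

    Uses biased (population-moment) skewness and excess kurtosis, the
    convention of the finite-sample correction term.  Raises on n < 4 or
    zero variance.
    """
    x = np.asarray(sample, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("Sarle's finite-sample b needs n >= 4")
    if np.ptp(x) == 0 or x.var() == 0:
        raise ValueError("zero variance sample: bimodality undefined")
    g1 = float(stats.skew(x, bias=True))
    g2 = float(stats.kurtosis(x, fisher=True, bias=True))
    b = (g1**2 + 1.0) / (g2 + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3)))
    if b > BIMODAL_THRESHOLD:
        modality = "bimodal"
    elif FLATTENED_BAND[0] <= b <= FLATTENED_BAND[1]:
        modality = "flattened"
    else:
        modality = "unimodal"
    return BimodalityReport(float(b), n, g1, g2, modality)


def sandpile_cp(
    matrix: ExpressionMatrix,
    t_a: float,
    t_b: float,
    n: int = 440,
    fluct: FluctuationTable | None = None,
    window: float = 0.25,
) -> SandpileProfile:
    """Detect the sandpile critical point for the change between t_a and t_b.

    Genes are grouped by their log expression change; the CP is the apex
    (local maximum of <ln eps(t_a)> with the largest peak prominence) of the
    profile restricted to |<change>| <= window.  A monotone profile or an
    empty window yields a no-transition result (cp = None, score 0) —
    the expected outcome for randomized nulls.
    """
    if n < 50:
        raise ValueError("sandpile grouping needs n >= 50 for coherence")
    if fluct is None:
        fluct = compute_rmsf(matrix)
    _, traj = group_by_key(fluct, matrix, key="expression_change", n=n, time_pair=(t_a, t_b))
    ja = matrix.index_of_time(t_a)
    # ascending in cm_change for peak search
    order = np.argsort(traj.cm_change, kind="stable")
    xc = traj.cm_change[order]
    y = traj.mean_ln[order, ja]
    nr = traj.cm_nrmsf[order]
    groups = traj.group_index[order]
    in_win = np.abs(xc) <= window
    cp = None
    score = 0.0
    ratio = 0.0
    if in_win.sum() >= 3:
        idx = np.nonzero(in_win)[0]
        peaks, props = signal.find_peaks(y[idx], prominence=0.0)
        if peaks.size:
            best = peaks[np.argmax(props["prominences"])]
            score = float(props["prominences"].max())
            g = idx[best]
            cp = CriticalPoint(float(y[g]), float(nr[g]), int(groups[g]), float(xc[g]))
            relief = float(y[idx].max() - y[idx].min())
            ratio = score / relief if relief > 0 else 0.0
    return SandpileProfile(xc, y, nr, cp, score, ratio)


def average_cp(
    matrix: ExpressionMatrix,
    pairs,
    n: int = 440,
    fluct: FluctuationTable | None = None,
    min_ratio: float = 0.0,
) -> dict:
    """Average CP coordinates over several (t_a, t_b) change pairs.

    Returns a dict with <nrmsf>_CP, ln<eps>_CP, the per-pair profiles, and
    the number of pairs in which a transition was detected (an apex counts
    only when its singularity ratio reaches ``min_ratio``).
    """
    if fluct is None:
        fluct = compute_rmsf(matrix)
    profiles = {pair: sandpile_cp(matrix, *pair, n=n, fluct=fluct) for pair in pairs}
    hits = [p.cp for p in profiles.values() if p.significant(min_ratio)]
    return {
        "nrmsf_cp": float(np.mean([c.nrmsf for c in hits])) if hits else None,
        "ln_eps_cp": float(np.mean([c.ln_eps for c in hits])) if hits else None,
        "n_detected": len(hits),
        "profiles": profiles,
    }


def _bin_edges(lo: float, hi: float, width: float) -> np.ndarray:
    lo_e = np.floor(lo / width) * width
    hi_e = np.ceil(hi / width) * width
    if hi_e <= lo_e + width / 2:  # degenerate range: one bin
        hi_e = lo_e + width
    return np.arange(lo_e, hi_e + width / 2, width)


def regulatory_density(
    matrix: ExpressionMatrix,
    genes,
    t_a: float,
    t_b: float,
    bin_width: float = 0.1,
    prominence_floor: float = 0.05,
) -> RegulatoryDensity:
    """Density in the regulatory space: x = ln(eps(t_b)/eps(t_a)), y = ln eps(t_a).

    The histogram (bin width 0.1 on both axes) is normalized to unit total
    mass.  Modes are strict 8-neighborhood local maxima above
    ``prominence_floor`` x (max density); the mode with the highest y is
    labelled HES, the one with the lowest y LES (when at least two exist).
    """
    if len(genes) == 0:
        raise ValueError("empty gene subset")
    if len(genes) < 50:
        logger.warning("regulatory_density: subset of %d genes is below the n = 50 coherence scale", len(genes))
    sub = matrix.subset(genes)
    ja, jb = sub.index_of_time(t_a), sub.index_of_time(t_b)
    y = sub.values[:, ja]
    x = sub.values[:, jb] - sub.values[:, ja]
    xe = _bin_edges(x.min(), x.max(), bin_width)
    ye = _bin_edges(y.min(), y.max(), bin_width)
    hist, xe, ye = np.histogram2d(x, y, bins=(xe, ye))
    dens = hist / hist.sum()
    # modes are found on a lightly smoothed surface (1-bin Gaussian) so that
    # shot noise in sparsely populated bins does not split a single mode
    smooth = ndimage.gaussian_filter(dens, sigma=1.0, mode="constant")
    floor = prominence_floor * smooth.max()
    padded = np.pad(smooth, 1, constant_values=-np.inf)
    core = padded[1:-1, 1:-1]
    is_max = np.ones_like(core, dtype=bool)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            is_max &= core > padded[1 + di : padded.shape[0] - 1 + di, 1 + dj : padded.shape[1] - 1 + dj]
    is_max &= core > floor
    xc = 0.5 * (xe[:-1] + xe[1:])
    yc = 0.5 * (ye[:-1] + ye[1:])
    modes = [
        {"x": float(xc[i]), "y": float(yc[j]), "density": float(dens[i, j]), "label": None}
        for i, j in np.argwhere(is_max)
    ]
    modes.sort(key=lambda m: -m["density"])
    if modes:
        hi = max(modes, key=lambda m: m["y"])
        lo = min(modes, key=lambda m: m["y"])
        hi["label"] = "HES"
        if lo is not hi:
            lo["label"] = "LES"
    return RegulatoryDensity(dens, xe, ye, modes)


def modality_scan(
    matrix: ExpressionMatrix,
    fluct: FluctuationTable,
    t_j: float,
    window: tuple,
) -> BimodalityReport:
    """Sarle bimodality of ln eps(t_j) restricted to an nrmsf window [lo, hi)."""
    lo, hi = window
    mask = (fluct.nrmsf >= lo) & (fluct.nrmsf < hi)
    genes = fluct.nrmsf.index[mask].tolist()
    if not genes:
        raise ValueError(f"nrmsf window [{lo}, {hi}) selects no genes")
    if len(genes) < 50:
        logger.warning("modality_scan: window [%g, %g) selects only %d genes", lo, hi, len(genes))
    sub = matrix.subset(genes)
    j = sub.index_of_time(t_j)
    return sarle_b(sub.values[:, j])


def modality_sequence(
    matrix: ExpressionMatrix,
    fluct: FluctuationTable,
    t_j: float,
    start: float,
    stop: float,
    width: float,
    step: float,
    min_genes: int = 50,
) -> pd.DataFrame:
    """Slide an nrmsf window from ``start`` down to ``stop`` and classify each.

    Rows are ordered by decreasing window center; windows selecting fewer
    than ``min_genes`` genes are skipped.  Across the critical point the
    sequence runs unimodal -> flattened -> bimodal.
    """
    rows = []
    center = start
    while center >= stop:
        lo, hi = center - width / 2, center + width / 2
        mask = (fluct.nrmsf >= lo) & (fluct.nrmsf < hi)
        if int(mask.sum()) >= min_genes:
            rep = modality_scan(matrix, fluct, t_j, (lo, hi))
            rows.append({"center": center, "lo": lo, "hi": hi, "n": rep.n, "b": rep.b, "modality": rep.modality})
        center = round(center - step, 12)
    return pd.DataFrame(rows)


def partition_states(fluct: FluctuationTable, thresholds: tuple = (0.08, 0.16)) -> CriticalPartition:
    """Label genes super / near / sub by nrmsf thresholds.

    Closed-below convention: a gene exactly at a threshold is assigned to the
    lower state (sub: nrmsf <= lo; near: lo < nrmsf <= hi; super: nrmsf > hi).
    """
    lo, hi = thresholds
    if not (0 < lo < hi < 1):
        raise ValueError("thresholds must satisfy 0 < lo < hi < 1")
    nr = fluct.nrmsf
    states = pd.Series(
        np.where(nr <= lo, "sub", np.where(nr <= hi, "near", "super")),
        index=nr.index,
        name="state",
    )
    return CriticalPartition(states, thresholds)


def fit_power_law(eps, nrmsf) -> PowerLawFit:
    """OLS fit of 1 - <nrmsf> = alpha <eps>^-beta on group averages.

    Regresses ln(1 - <nrmsf>) on ln<eps>: slope = -beta, intercept = ln alpha.
    Reports r^2, the two-sided slope p-value and a 95% CI for beta.
    """
    eps = np.asarray(eps, dtype=float)
    nr = np.asarray(nrmsf, dtype=float)
    if eps.size < 3:
        raise ValueError("power-law fit needs at least 3 points")
    if np.any(eps <= 0):
        raise ValueError("nonpositive group-average expression")
    if np.any(nr >= 1):
        raise ValueError("group-average nrmsf must be < 1")
    x = np.log(eps)
    y = np.log(1.0 - nr)
    res = stats.linregress(x, y)
    beta = -res.slope
    dof = eps.size - 2
    tcrit = stats.t.ppf(0.975, dof)
    ci = (beta - tcrit * res.stderr, beta + tcrit * res.stderr)
    return PowerLawFit(
        alpha=float(np.exp(res.intercept)),
        beta=float(beta),
        r2=float(res.rvalue**2),
        p_value=float(res.pvalue),
        beta_stderr=float(res.stderr),
        beta_ci=(float(ci[0]), float(ci[1])),
        n_points=int(eps.size),
    )


def fit_power_law_deab(deab_points) -> PowerLawFit:
    """Fit the power law from DEAB coordinates (ln<eps>, ln(1 - <nrmsf>))."""
    pts = np.asarray(deab_points, dtype=float)
    return fit_power_law(np.exp(pts[:, 0]), 1.0 - np.exp(pts[:, 1]))
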
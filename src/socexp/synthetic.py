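"""Synthetic expression time courses with known critical-state structure.

The generator emulates the statistical features the SOC analysis assumes,
with exact ground truth for every recovery test:

* three latent fluctuation strata (super / near / sub-critical) arranged in
  chromosomal runs; genes within a run share the stratum, a common target
  fluctuation level and (in the sub stratum) a common high- or
  low-expression component — a chromatin-domain-like coherence that makes
  same-state barcodes aggregate coherently while state-mixing nulls dilute;
* per-gene target nrmsf drawn around the run level within the stratum's
  range; the per-gene linear-scale fluctuation amplitude is enforced
  *exactly* (the temporal pattern is standardized to zero mean and unit
  population SD before scaling), so the empirical nrmsf equals the planted
  target;
* a power-law coupling between mean expression and fluctuation,
  1 - nrmsf = alpha * mean_eps^-beta, plateaued above a configurable nrmsf
  cap (the law has no bounded mean as nrmsf -> 1);
* coherent anti-phase oscillation of the stratum centers of mass (the
  sub-critical low-expression component swings opposite to the
  super-critical stratum) on top of memoryless gene-level noise;
* a bimodal expression marginal in the sub-critical stratum (high- and
  low-expression components of equal weight and unit linear-scale mean).

Expression is assembled on the linear scale,

    eps_i(t_j) = mean_i + nu_i * R * z_i(t_j),

with z_i the standardized mix of the stratum waveform and white noise,
nu_i the target nrmsf and R the target maximum rmsf; values are stored as
natural logs.  Gene order is chromosomal order; ``generate_annotation``
assigns the coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneAnnotation

#: the study-like sampling grid, minutes (0 .. 72 h, log-like spacing)
DEFAULT_TIMES = (0, 10, 15, 20, 30, 45, 60, 90, 120, 180, 240, 360, 480, 720, 1440, 2160, 2880, 4320)

STATES = ("super", "near", "sub")


@dataclass
class SyntheticConfig:
    """Study conditions for the generator; the defaults are the conditions
    every recovery test runs under."""

    n_genes: int = 20000
    times: tuple = DEFAULT_TIMES
    # stratum proportions (sum to 1); defaults follow the 3269/9707/9059 split
    proportions: dict = field(default_factory=lambda: {"super": 0.1484, "near": 0.4405, "sub": 0.4111})
    # target-nrmsf ranges per stratum
    nrmsf_ranges: dict = field(
        default_factory=lambda: {"super": (0.16, 1.0), "near": (0.08, 0.16), "sub": (0.01, 0.08)}
    )
    super_tail_shape: float = 4.0      # Beta(1, shape) tail of super run-level nrmsf toward 1
    run_nrmsf_jitter: float = 0.15     # member nrmsf SD, as a fraction of the stratum range
    # planted power law 1 - nrmsf = alpha * eps^-beta, plateaued above the cap
    powerlaw_alpha: float = 1.27
    powerlaw_beta: float = 0.16
    powerlaw_nrmsf_cap: float = 0.5
    max_rmsf: float = 2.64             # genome-wide rmsf normalization target
    # coherent oscillation of stratum centers of mass
    waveform: str = "sin"              # 'sin' or 'square'
    period_samples: float = 8.0        # waveform period in sample indices (log-like grid)
    phases: dict = field(default_factory=lambda: {"super": math.pi, "near": 0.0, "sub": 0.0})
    osc_var_fraction: dict = field(default_factory=lambda: {"super": 0.7, "near": 0.05, "sub": 0.6})
    # sub-critical bimodal mixture: equal-weight components with unit linear mean
    sub_les_factor: float = 0.35       # low-expression component, linear multiplier
    sub_hes_factor: float = 1.65       # high-expression component
    sub_component_jitter: float = 0.10  # ln-scale SD of member jitter within each component
    expr_jitter: float = 0.30          # ln-scale SD of the run-level mean-one jitter, super/near
    member_expr_jitter: float = 0.10   # ln-scale SD of within-run member jitter, super/near
    domain_noise_fraction: float = 0.5  # share of stochastic variance coherent within a run
    # chromosome layout
    n_chroms: int = 6
    mean_run_length: dict = field(default_factory=lambda: {"super": 1.3, "near": 2.0, "sub": 2.5})
    gene_length_median: float = 27000.0  # bp; protein-coding-like
    gene_length_sigma: float = 0.8       # ln-scale SD of gene length
    gap_median: float = 5000.0
    gap_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"state proportions must sum to 1, got {total}")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0 < self.powerlaw_nrmsf_cap < 1:
            raise ValueError("powerlaw_nrmsf_cap must be in (0, 1)")
        for s in STATES:
            lo, hi = self.nrmsf_ranges[s]
            if not 0 < lo < hi <= 1:
                raise ValueError(f"bad nrmsf range for {s}: ({lo}, {hi})")


@dataclass
class SyntheticTruth:
    """Ground truth sufficient to score every recovery test."""

    genes: pd.DataFrame      # state, component, nrmsf, mean_eps, osc_fraction, run_id (chromosomal order)
    waveforms: dict          # state -> standardized waveform over the grid
    alpha: float
    beta: float
    nrmsf_cap: float
    max_rmsf: float
    mean_run_length: dict
    seed: int

    def state_counts(self) -> dict:
        c = self.genes.state.value_counts()
        return {s: int(c.get(s, 0)) for s in STATES}

    def run_lengths(self, state: str) -> np.ndarray:
        g = self.genes[self.genes.state == state]
        return g.groupby("run_id").size().to_numpy()


def _standardize(v: np.ndarray, axis=-1) -> np.ndarray:
    m = v.mean(axis=axis, keepdims=True)
    s = v.std(axis=axis, ddof=0, keepdims=True)
    return (v - m) / s


def _reflect(v: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect values into (lo, hi) without piling mass on the boundaries.

    Stratum boundaries coincide with the partition thresholds, so an atom at
    a boundary would make labels float-rounding-dependent; a small interior
    margin keeps members strictly inside.
    """
    span = hi - lo
    margin = 1e-9 * span
    out = np.abs(np.mod(v - lo, 2 * span))
    out = np.where(out > span, 2 * span - out, out) + lo
    return np.clip(out, lo + margin, hi - margin)


def _planted_mean(nu: np.ndarray, alpha: float, beta: float, cap: float) -> np.ndarray:
    """Mean expression from the planted power law, plateaued above the cap."""
    nu_eff = np.minimum(nu, cap)
    return (alpha / (1.0 - nu_eff)) ** (1.0 / beta)


def _plan_runs(rng: np.random.Generator, counts: dict, mean_run: dict) -> list:
    """Sequence of (state, length) runs using all genes; successive runs
    differ in state where possible, so planted runs are maximal."""
    remaining = dict(counts)
    runs = []
    prev = None
    while any(remaining.values()):
        avail = [s for s in STATES if remaining[s] and s != prev] or [s for s in STATES if remaining[s]]
        weights = np.array([remaining[s] for s in avail], dtype=float)
        state = avail[int(rng.choice(len(avail), p=weights / weights.sum()))]
        m = mean_run[state]
        length = 1 if m <= 1 else int(rng.geometric(1.0 / m))
        length = min(length, remaining[state])
        runs.append((state, length))
        remaining[state] -= length
        prev = state
    return runs


def generate_expression(config: SyntheticConfig):
    """Generate an (ExpressionMatrix, SyntheticTruth) pair.

    Same seed gives bit-identical output.  Raises with a diagnostic when the
    configuration is infeasible (a fluctuation amplitude large enough to
    drive linear expression nonpositive).
    """
    rng = np.random.default_rng(config.seed)
    times = np.asarray(config.times, dtype=float)
    T1 = times.size
    n = config.n_genes

    counts = {s: int(round(config.proportions[s] * n)) for s in STATES}
    counts["sub"] += n - sum(counts.values())  # rounding remainder

    runs = _plan_runs(rng, counts, config.mean_run_length)
    states = np.empty(n, dtype=object)
    run_id = np.empty(n, dtype=int)
    nu = np.empty(n)
    component = np.array([""] * n, dtype=object)
    factor = np.empty(n)
    i = 0
    for rid, (state, length) in enumerate(runs):
        lo, hi = config.nrmsf_ranges[state]
        if state == "super":
            center = lo + (hi - lo) * rng.beta(1.0, config.super_tail_shape)
        else:
            center = rng.uniform(lo, hi)
        jitter_sd = config.run_nrmsf_jitter * (hi - lo) if state != "super" else 0.05
        member_nu = _reflect(center + rng.normal(0.0, jitter_sd, length), lo, hi)
        if state == "sub":
            comp = "LES" if rng.random() < 0.5 else "HES"
            base = config.sub_les_factor if comp == "LES" else config.sub_hes_factor
            jit = rng.normal(-config.sub_component_jitter**2 / 2.0, config.sub_component_jitter, length)
            member_factor = base * np.exp(jit)
            member_comp = comp
        else:
            # run-level expression context (domains share it) + member jitter
            run_c = rng.normal(-config.expr_jitter**2 / 2.0, config.expr_jitter)
            jit = rng.normal(-config.member_expr_jitter**2 / 2.0, config.member_expr_jitter, length)
            member_factor = np.exp(run_c + jit)
            member_comp = ""
        sl = slice(i, i + length)
        states[sl] = state
        run_id[sl] = rid
        nu[sl] = member_nu
        component[sl] = member_comp
        factor[sl] = member_factor
        i += length
    # pin the genome-wide maximum so that empirical nrmsf == planted target
    nu[np.argmax(nu)] = 1.0

    mean_eps = _planted_mean(nu, config.powerlaw_alpha, config.powerlaw_beta, config.powerlaw_nrmsf_cap) * factor

    idx = np.arange(T1, dtype=float)
    waveforms = {}
    for s in STATES:
        if config.waveform == "sin":
            w = np.sin(2.0 * math.pi * idx / config.period_samples + config.phases[s])
        elif config.waveform == "square":
            # exact two-level switching (phase position decides the level)
            frac = np.mod(idx / config.period_samples + config.phases[s] / (2.0 * math.pi), 1.0)
            w = np.where(frac < 0.5, 1.0, -1.0)
        else:
            raise ValueError(f"unknown waveform {config.waveform!r}")
        waveforms[s] = _standardize(w)

    rho = np.array([config.osc_var_fraction[s] for s in states])
    # only the swinging low-expression component oscillates in the sub stratum
    rho[(states == "sub") & (component != "LES")] = 0.0

    # stochastic part: a domain-coherent component shared within each run
    # (chromatin domains act as dynamical units) plus gene-level noise
    kappa = config.domain_noise_fraction
    run_noise = rng.standard_normal((len(runs), T1))
    noise = math.sqrt(kappa) * run_noise[run_id] + math.sqrt(1.0 - kappa) * rng.standard_normal((n, T1))
    wave = np.vstack([waveforms[s] for s in states])
    pattern = np.sqrt(rho)[:, None] * wave + np.sqrt(1.0 - rho)[:, None] * noise
    z = _standardize(pattern, axis=1)

    eps = mean_eps[:, None] + (nu * config.max_rmsf)[:, None] * z
    if np.any(eps <= 0):
        gi, tj = np.argwhere(eps <= 0)[0]
        raise ValueError(
            "infeasible config: nonpositive linear expression "
            f"(gene {gi}, state {states[gi]}, nrmsf {nu[gi]:.3f}, mean {mean_eps[gi]:.3f}, "
            f"time index {tj}); reduce fluctuation amplitudes or raise means"
        )

    gene_ids = [f"g{i:06d}" for i in range(n)]
    matrix = ExpressionMatrix(gene_ids, times, np.log(eps), "natural_log")
    genes = pd.DataFrame(
        {
            "state": states,
            "component": component,
            "nrmsf": nu,
            "mean_eps": mean_eps,
            "osc_fraction": rho,
            "run_id": run_id,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    truth = SyntheticTruth(
        genes=genes,
        waveforms=waveforms,
        alpha=config.powerlaw_alpha,
        beta=config.powerlaw_beta,
        nrmsf_cap=config.powerlaw_nrmsf_cap,
        max_rmsf=config.max_rmsf,
        mean_run_length=dict(config.mean_run_length),
        seed=config.seed,
    )
    return matrix, truth


def generate_annotation(config: SyntheticConfig, truth: SyntheticTruth) -> GeneAnnotation:
    """Assign chromosomal coordinates to the (already run-ordered) genes.

    Genes are laid down in index order across ``n_chroms`` chromosomes of
    roughly equal gene count; gene lengths and intergenic gaps are lognormal
    and genes do not overlap.  Uses a seed derived from the config seed, so
    expression and layout are jointly reproducible.
    """
    rng = np.random.default_rng(config.seed + 1000)
    n = len(truth.genes)
    per_chrom = math.ceil(n / config.n_chroms)
    lengths = rng.lognormal(math.log(config.gene_length_median), config.gene_length_sigma, n).astype(int) + 1
    gaps = rng.lognormal(math.log(config.gap_median), config.gap_sigma, n).astype(int) + 1
    rows = []
    cursor = 0
    for i, gid in enumerate(truth.genes.index):
        chrom_no = i // per_chrom + 1
        if i % per_chrom == 0:
            cursor = 0
        start = cursor + gaps[i]
        rows.append({"chrom": f"chr{chrom_no}", "start": int(start), "end": int(start + lengths[i]), "gene_id": gid})
        cursor = start + lengths[i]
    return GeneAnnotation(pd.DataFrame(rows))
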
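"""Orchestration of the four-step systemic mean-field procedure.

Step i   locate the critical point (CP) by sandpile change-grouping over the
         configured time pairs;
step ii  sort and group the whole expression by nrmsf;
step iii confirm the CP against the divergence onset of the temporal DEAB
         curves (avalanche-like distribution);
step iv  confirm the unimodal -> flattened -> bimodal modality transition by
         scanning nrmsf windows across the CP.

The report is a plain dict (JSON-serializable apart from the embedded
profile objects) with a pass/fail flag per confirmation; a failed stage
marks later stages skipped rather than raising.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .criticality import average_cp, fit_power_law, modality_sequence, partition_states
from .fluctuation import compute_rmsf, deab_curve, group_by_key
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    group_size: int = 440
    barcode_group_size: int = 182
    thresholds: tuple = (0.08, 0.16)
    cp_pairs: tuple = ((10, 15), (15, 20), (20, 30))
    deab_times: tuple = (0, 10, 15, 20)
    rmsf_scale: str = "linear"
    modality_window_width: float = 0.02
    modality_step: float = 0.01
    onset_group_tolerance: int = 2
    powerlaw_nrmsf_max: float = 1.0
    min_singularity_ratio: float = 0.5  # apex must carry half the profile relief
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.thresholds
        if not (0 < lo < hi < 1):
            raise ValueError("thresholds must satisfy 0 < lo < hi < 1")
        if self.group_size < 2 or self.barcode_group_size < 2:
            raise ValueError("group sizes must be >= 2")
        for pair in self.cp_pairs:
            if len(pair) != 2:
                raise ValueError(f"bad CP time pair {pair!r}")

    def as_dict(self) -> dict:
        return {
            "group_size": self.group_size,
            "barcode_group_size": self.barcode_group_size,
            "thresholds": list(self.thresholds),
            "cp_pairs": [list(p) for p in self.cp_pairs],
            "deab_times": list(self.deab_times),
            "rmsf_scale": self.rmsf_scale,
            "modality_window_width": self.modality_window_width,
            "modality_step": self.modality_step,
            "onset_group_tolerance": self.onset_group_tolerance,
            "powerlaw_nrmsf_max": self.powerlaw_nrmsf_max,
            "min_singularity_ratio": self.min_singularity_ratio,
            "seed": self.seed,
        }


def _divergence_onset(traj, matrix, times) -> dict:
    """Group index where between-time DEAB separation first exceeds twice its
    median, walking from the low-nrmsf (scaling) side."""
    cols = [matrix.index_of_time(t) for t in times]
    xs = traj.ln_mean[:, cols]  # (k, n_times)
    spread = xs.max(axis=1) - xs.min(axis=1)
    med = float(np.median(spread))
    onset = None
    if med > 0:
        # group k (lowest nrmsf) .. group 1 (highest)
        for g in range(len(spread) - 1, -1, -1):
            if spread[g] > 2.0 * med:
                onset = g + 1  # 1-based group index
                break
    return {"spread": spread, "median": med, "onset_group": onset}


def run_procedure(matrix: ExpressionMatrix, config: RunConfig | None = None) -> dict:
    """Run the systemic mean-field procedure and report the confirmations.

    Returns a dict with ``schema_version``, the echoed config, per-step
    results and ``confirmed`` flags.  Stage errors mark the step failed and
    skip the remaining steps.
    """
    config = config or RunConfig()
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": config.as_dict(),
        "steps": {},
        "soc_detected": False,
    }
    fluct = compute_rmsf(matrix, config.rmsf_scale)
    logger.info("run_procedure: %d genes, %d time points", matrix.n_genes, matrix.n_times)

    # step i: sandpile CP over the configured change pairs
    try:
        cp = average_cp(
            matrix,
            config.cp_pairs,
            n=config.group_size,
            fluct=fluct,
            min_ratio=config.min_singularity_ratio,
        )
    except Exception as exc:  # pragma: no cover - defensive
        report["steps"]["cp"] = {"ok": False, "error": str(exc)}
        return report
    # the CP is temporally invariant: demand the apex in a majority of pairs
    step_i = {
        "ok": cp["n_detected"] >= (len(config.cp_pairs) + 1) // 2,
        "nrmsf_cp": cp["nrmsf_cp"],
        "ln_eps_cp": cp["ln_eps_cp"],
        "n_detected": cp["n_detected"],
        "n_pairs": len(config.cp_pairs),
        "singularity_scores": {str(pair): prof.singularity_score for pair, prof in cp["profiles"].items()},
    }
    report["steps"]["cp"] = step_i
    if not step_i["ok"]:
        report["steps"]["cp"]["note"] = "no sandpile transition detected; SOC absent"
        return report

    # step ii: nrmsf grouping
    grouping, traj = group_by_key(fluct, matrix, key="nrmsf_desc", n=config.group_size)
    report["steps"]["grouping"] = {
        "ok": True,
        "k": grouping.k,
        "n": grouping.n,
        "dropped": len(grouping.dropped),
    }

    # step iii: DEAB divergence onset sits at the CP
    onset = _divergence_onset(traj, matrix, config.deab_times)
    cp_group = int(np.argmin(np.abs(traj.cm_nrmsf - step_i["nrmsf_cp"]))) + 1
    onset_ok = onset["onset_group"] is not None and abs(onset["onset_group"] - cp_group) <= config.onset_group_tolerance
    deab0 = deab_curve(traj, matrix, config.deab_times[0])
    keep = (1.0 - np.exp(deab0[:, 1])) <= config.powerlaw_nrmsf_max
    power_law = fit_power_law(np.exp(deab0[keep, 0]), 1.0 - np.exp(deab0[keep, 1]))
    report["steps"]["deab"] = {
        "ok": onset_ok,
        "onset_group": onset["onset_group"],
        "cp_group": cp_group,
        "tolerance": config.onset_group_tolerance,
        "power_law": {
            "alpha": power_law.alpha,
            "beta": power_law.beta,
            "r2": power_law.r2,
            "p_value": power_law.p_value,
        },
    }

    # step iv: modality transition across the CP
    nrmsf_cp = step_i["nrmsf_cp"]
    start = min(nrmsf_cp + 0.06, float(fluct.nrmsf.max()))
    stop = max(0.01, float(fluct.nrmsf.min()))
    seq = modality_sequence(
        matrix,
        fluct,
        config.cp_pairs[0][0],
        start=start,
        stop=stop,
        width=config.modality_window_width,
        step=config.modality_step,
    )
    classes = seq.modality.tolist()
    has_unimodal_high = "unimodal" in classes and classes.index("unimodal") < len(classes)
    has_bimodal_low = "bimodal" in classes
    ordered = True
    if has_unimodal_high and has_bimodal_low:
        last_uni = max(i for i, c in enumerate(classes) if c == "unimodal")
        first_bi = min(i for i, c in enumerate(classes) if c == "bimodal")
        ordered = last_uni < first_bi
    transitional = seq[(seq.b >= 0.45) & (seq.b <= 5.0 / 9.0)]
    step_iv_ok = bool(has_unimodal_high and has_bimodal_low and ordered)
    report["steps"]["modality"] = {
        "ok": step_iv_ok,
        "windows": seq.to_dict("records"),
        "flattened_centers": transitional.center.tolist(),
        "nrmsf_cp": nrmsf_cp,
    }

    partition = partition_states(fluct, config.thresholds)
    report["steps"]["partition"] = {"ok": True, "counts": partition.counts}
    report["soc_detected"] = bool(step_i["ok"] and onset_ok and step_iv_ok)
    report["confirmations"] = {
        "sandpile_cp": step_i["ok"],
        "deab_divergence_onset": onset_ok,
        "modality_transition": step_iv_ok,
    }
    return report
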
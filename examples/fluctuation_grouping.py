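"""Fluctuation statistics and mean-field grouping.

Generates a synthetic expression time course, computes per-gene rmsf /
nrmsf, groups genes by fluctuation and prints the DEAB curve ends and the
fitted power law between group-average expression and fluctuation.
"""

import numpy as np

from socexp import (
    SyntheticConfig,
    compute_rmsf,
    deab_curve,
    fit_power_law,
    generate_expression,
    group_by_key,
)

matrix, truth = generate_expression(SyntheticConfig(n_genes=8000, seed=11))
fluct = compute_rmsf(matrix)
print(f"{matrix.n_genes} genes, {matrix.n_times} time points; max rmsf = {fluct.max_rmsf:.2f}")

grouping, traj = group_by_key(fluct, matrix, key="nrmsf_desc", n=200)
print(f"{grouping.k} groups of {grouping.n} genes ({len(grouping.dropped)} remainder genes dropped)")

pts = deab_curve(traj, matrix, t_j=0)
print(f"DEAB curve: ln<eps> from {pts[:, 0].min():.2f} to {pts[:, 0].max():.2f} across groups")

keep = (1.0 - np.exp(pts[:, 1])) <= 0.45  # scaling region
fit = fit_power_law(np.exp(pts[keep, 0]), 1.0 - np.exp(pts[keep, 1]))
print(f"power law 1-<nrmsf> = alpha <eps>^-beta: alpha = {fit.alpha:.3f}, beta = {fit.beta:.3f} (r2 = {fit.r2:.3f})")
print(f"(planted: alpha = {truth.alpha}, beta = {truth.beta})")
print("-> group-average fluctuation and expression are power-law coupled; the")
print("   fitted exponent recovers the structure planted in the generator.")
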
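"""The four-step systemic mean-field procedure, end to end.

Runs critical-point detection, nrmsf grouping, the DEAB divergence-onset
confirmation and the modality-transition confirmation, and prints the
machine-readable report summary.
"""

from socexp import RunConfig, SyntheticConfig, generate_expression, run_procedure

matrix, truth = generate_expression(SyntheticConfig(seed=11))
report = run_procedure(matrix, RunConfig())

cp = report["steps"]["cp"]
print(f"step i   sandpile CP: <nrmsf>_CP = {cp['nrmsf_cp']:.3f}, ln<eps>_CP = {cp['ln_eps_cp']:.2f} "
      f"({cp['n_detected']}/{cp['n_pairs']} pairs)")
g = report["steps"]["grouping"]
print(f"step ii  grouping: {g['k']} groups of {g['n']} genes")
deab = report["steps"]["deab"]
print(f"step iii DEAB divergence onset at group {deab['onset_group']} vs CP group {deab['cp_group']} "
      f"(tolerance +-{deab['tolerance']}); power law beta = {deab['power_law']['beta']:.3f}")
flat = report["steps"]["modality"]["flattened_centers"]
print(f"step iv  modality transition confirmed: {report['confirmations']['modality_transition']} "
      f"(flattened windows near nrmsf {flat if flat else 'n/a'})")
print("confirmations:", report["confirmations"])
print("SOC detected:", report["soc_detected"])
print("-> all three confirmations agree: the expression dynamics carry a")
print("   self-organized critical point with its mean-field signatures.")
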
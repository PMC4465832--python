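"""Sandpile critical point and the modality transition.

Regroups genes by expression change to locate the sandpile apex (the
critical point), partitions genes into critical states by nrmsf and scans
expression windows to show the unimodal -> bimodal transition.
"""

from socexp import (
    SyntheticConfig,
    compute_rmsf,
    generate_expression,
    modality_sequence,
    partition_states,
    sandpile_cp,
)

matrix, truth = generate_expression(SyntheticConfig(seed=11))
fluct = compute_rmsf(matrix)

for pair in ((10, 15), (15, 20), (20, 30)):
    prof = sandpile_cp(matrix, *pair, n=440, fluct=fluct)
    cp = prof.cp
    print(
        f"change {pair[0]:>2}-{pair[1]:<2} min: CP at ln(eps) = {cp.ln_eps:.2f}, "
        f"nrmsf = {cp.nrmsf:.3f} (singularity score {prof.singularity_score:.2f})"
    )
print("-> the apex of expression vs expression change sits at ~zero change,")
print("   the balance point of up- and down-regulation, at a stable nrmsf.")

partition = partition_states(fluct, thresholds=(0.08, 0.16))
print("state counts:", partition.counts)

seq = modality_sequence(matrix, fluct, t_j=10, start=0.14, stop=0.02, width=0.02, step=0.02)
for row in seq.itertuples():
    print(f"  nrmsf window [{row.lo:.2f}, {row.hi:.2f}): b = {row.b:.2f} ({row.modality}, n = {row.n})")
print("-> Sarle's b rises above 5/9 as windows cross into the low-fluctuation")
print("   (sub-critical) stratum: unimodal high-variance genes, bimodal static genes.")
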
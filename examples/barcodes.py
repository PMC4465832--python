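"""Chromosomal barcode genes and their randomization null.

Builds maximal same-state runs along synthetic chromosomes, summarizes
their bp correlation lengths, reruns the sandpile test at barcode level
and contrasts it with the state-mixing random-barcode null.
"""

import numpy as np

from socexp import (
    SyntheticConfig,
    build_barcodes,
    compute_rmsf,
    generate_annotation,
    generate_expression,
    partition_states,
    random_barcode_II,
    sandpile_cp,
)

config = SyntheticConfig(seed=11)
matrix, truth = generate_expression(config)
partition = partition_states(compute_rmsf(matrix))
annotation = generate_annotation(config, truth)

bset = build_barcodes(partition, annotation)
print(f"{len(bset)} barcodes from {matrix.n_genes} genes; per state: {bset.state_counts}")
for state in ("super", "near", "sub"):
    lengths = [bc.correlation_length for bc in bset.barcodes if bc.state == state]
    print(f"  {state:>5}: median correlation length {np.median(lengths)/1e3:.0f} kbp, "
          f"single-gene fraction {bset.single_gene_fraction(state):.2f}")

pairs = ((10, 15), (15, 20), (20, 30))
bc_matrix = bset.to_expression_matrix(matrix)
structured = np.mean([sandpile_cp(bc_matrix, *p, n=182).singularity_score for p in pairs])
null = random_barcode_II(partition, annotation, seed=11)
null_matrix = null.to_expression_matrix(matrix)
randomized = np.mean([sandpile_cp(null_matrix, *p, n=182).singularity_score for p in pairs])
print(f"sandpile singularity: structured barcodes {structured:.2f}, "
      f"randomized null {randomized:.2f} ({100*randomized/structured:.0f}%)")
print("-> mixing critical states along the chromosome destroys the sandpile")
print("   transition; the barcode organization is not incidental.")
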
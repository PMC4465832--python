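# socexp — self-organized criticality in expression time courses

`socexp` analyzes genome-wide expression time series (bulk microarray or
RNA-seq style matrices: N genes × ordered time points) for signatures of
self-organized criticality (SOC): a whole-genome phase transition in which
gene ensembles sorted by temporal fluctuation split into super-, near- and
sub-critical states around a sandpile-like critical point. It is a library
for computational biologists who want to apply (or stress-test) this
mean-field analysis on their own time courses, with a fully specified
synthetic-data generator standing in for the original microarray study.

## The statistics at the core

For gene *i* with linear expression ε\_i(t\_j) over T+1 time points, the
order parameter is the root-mean-square fluctuation

    rmsf_i = sqrt( (1/(T+1)) Σ_j (ε_i(t_j) − ε̄_i)² ),   nrmsf_i = rmsf_i / max_i rmsf_i .

Genes sorted by nrmsf (or by expression change between two times) are cut
into k equal groups of n genes; group centers of mass over time are the
mean field. The analysis then provides:

* **Sandpile critical point** — regroup by expression change; the apex of
  ⟨ln ε⟩ vs ⟨Δln ε⟩ near zero change is the critical point (CP), where up-
  and down-regulation balance.
* **Modality transition** — Sarle's finite-sample bimodality coefficient
  b = (g₁²+1)/(g₂ + 3(n−1)²/((n−2)(n−3))) classifies expression windows as
  unimodal, flattened (transition) or bimodal (b > 5/9) across the CP.
* **DEAB power law** — group coordinates {ln⟨ε⟩, ln(1−⟨nrmsf⟩)} follow
  1 − ⟨nrmsf⟩ = α⟨ε⟩^−β, the scaling signature of SOC.
* **Scaled correlations** — the between-profiles correlation of Eq-7 form
  with zero / group-CM / whole-CM references, focal-point detection, and
  the center-of-mass algebra P(t_j; t_{j+1}−t_j) ≈ α λ_j (⟨x(t_j)⟩−⟨x(t_{j+1})⟩)
  with λ_j = N(t_j)/N(t_{j+1}−t_j), capturing coherent stochastic oscillation.
* **Barcode genes** — maximal runs of chromosomally consecutive genes in
  one critical state, their bp correlation lengths, and two randomization
  nulls that destroy the state organization.

## Worked example

```bash
python examples/critical_point.py
```

prints (seeded synthetic data, 20 000 genes × 18 time points):

```
change 10-15 min: CP at ln(eps) = 3.15, nrmsf = 0.213 (singularity score 1.27)
change 15-20 min: CP at ln(eps) = 3.20, nrmsf = 0.225 (singularity score 1.53)
change 20-30 min: CP at ln(eps) = 3.14, nrmsf = 0.205 (singularity score 1.28)
state counts: {'super': 2968, 'near': 8810, 'sub': 8222}
  nrmsf window [0.13, 0.15): b = 0.33 (unimodal, n = 2192)
  nrmsf window [0.09, 0.11): b = 0.33 (unimodal, n = 2172)
  nrmsf window [0.07, 0.09): b = 0.68 (bimodal, n = 2262)
  nrmsf window [0.01, 0.03): b = 0.93 (bimodal, n = 2326)
```

The sandpile apex sits at near-zero expression change with a temporally
stable nrmsf — the critical point. Below it (static, sub-critical genes)
the expression distribution is bimodal (b > 5/9 = 0.556); above it the
distribution is unimodal. The other scripts in `examples/` walk through
fluctuation grouping and the power law, correlation dynamics and the CM
algebra, barcode construction with its randomization null, and the full
four-step procedure (`socexp.run_procedure`).

Real data enter through `socexp.read_expression` (TSV, linear / log2 /
natural-log scale tags) and `socexp.read_annotation` (BED-like), and flow
through the same functions.

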
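# Methods

## Scope and data model

`socexp` implements a mean-field analysis of expression time courses.
Internally every matrix holds natural-log expression x_i(t_j) = ln ε_i(t_j)
for N ≥ 2 genes at T+1 ≥ 3 strictly increasing sampling times (minutes,
first = 0); linear and log2 inputs are converted on load. All formulas that
the analysis quotes in linear units (notably rmsf) exponentiate internally.
Annotation coordinates are BED-style 0-based half-open; strand is ignored
for ordering, and overlapping genes order by (start, end, id).

## Fluctuation statistics and grouping

rmsf uses the population denominator 1/(T+1) on linear ε; nrmsf divides by
the genome-wide maximum, so exactly one gene sits at 1. A configuration
switch (`rmsf_scale='ln'`) evaluates the fluctuation on the log scale for
sensitivity checks; it is not the default because the statistic is defined
on the expression unit itself.

Grouping sorts by the key (nrmsf, or log fold change between a supplied
time pair), descending, ties broken by gene id (stable and reproducible);
k = ⌊N/n⌋ equal groups of n; the N mod n remainder is dropped from the
lowest-key tail and logged. Group trajectories store both ⟨ln ε⟩ (the CM
proper) and ln⟨ε⟩; DEAB curves default to ln⟨ε⟩ on the x axis — the log of
the group's average expression — with ⟨ln ε⟩ exposed as an option, since
either average is defensible and the difference is a Jensen term that is
small within narrow-nrmsf groups.

## Critical point and modality

The sandpile test regroups by expression change and looks for the apex of
⟨ln ε⟩ vs ⟨Δ ln ε⟩ within a window |⟨Δ⟩| ≤ 0.25 (natural-log units,
configurable): the apex is the interior local maximum with the largest
peak prominence (`scipy.signal.find_peaks`); the prominence is the
**singularity score**, and the score divided by the profile's relief
inside the window is a scale-free **singularity ratio**. A monotone
profile yields a no-transition result. The full procedure demands the
apex in a majority of the configured change pairs (default 10–15, 15–20,
20–30 min) before declaring a CP — the critical point is supposed to be
temporally invariant, and randomized inputs that produce a spurious bump
at one pair fail this test.

Sarle's finite-sample b uses population-moment skewness and excess
kurtosis. Modality classes: bimodal for b > 5/9; flattened for
0.45 ≤ b ≤ 5/9 (a declared band around the flattened exemplar b ≈ 0.49 —
no threshold for "flattened" exists in the literature); unimodal
otherwise. Windows are half-open in nrmsf, [lo, hi), and state partition
thresholds are closed below (a gene exactly at 0.08 is sub-critical;
defaults 0.08 / 0.16).

Regulatory-space densities use 0.1-wide bins on both axes (change on x,
log expression on y), normalized to unit mass. Mode detection runs on a
1-bin Gaussian smoothing of the histogram (raw densities are reported) so
that shot noise cannot split one mode into neighboring local maxima; modes
must exceed 5% of the smoothed maximum. The highest-y mode is labelled
HES, the lowest LES.

The power-law fit is OLS of ln(1−⟨nrmsf⟩) on ln⟨ε⟩ (slope = −β,
intercept = ln α) with r², slope p-value and a 95% t-based CI on β. The
fit is scale-consistent: rescaling ε by c maps α to αc^β and leaves β.

## Correlation dynamics

All correlations are between profiles — genes are the statistical units.
The scaled correlation takes a reference per vector: none (zero vector;
cosine form), the vector's own mean (this reproduces the ordinary
product-moment correlation exactly, which is the oracle identity used in
tests), or the whole-expression mean at that time. Series P(t0;tj),
P(tj;tj+1), P(tj;tj+1−tj), P(t1−t0;tj+1−tj) are computed on ln-scale
change vectors; an index with a constant vector is NaN.

The CM algebra computes deviation norms N(t_j) (expression) and
N(t_{j+1}−t_j) (change) and the ratios

    λ_j = N(t_j)/N(t_{j+1}−t_j),  γ_j = N(t_{j+1})/N(t_j),
    β_j = α (2N(t_1) − N(t_0)) / (N(t_1−t_0) N(t_{j+1}−t_j)).

The printed fraction bars of these ratios are typographically ambiguous in
the source material; the orientation above is the one validated against
the exact-Pearson series: with it, the first-order identity
γ_j P(t0;t_{j+1}) − P(t0;t_j) ≈ α(⟨x(t_j)⟩−⟨x(t_{j+1})⟩) holds to
correlation 1.0 and matching scale on coherent synthetic ensembles, and
the approximation α λ_j (⟨x(t_j)⟩−⟨x(t_{j+1})⟩) tracks the exact
P(t_j;t_{j+1}−t_j) series at correlation ≥ 0.99. The companion relation
⟨x(t_j)⟩−⟨x(t_{j+1})⟩ ≈ (1/α)(λ_j−1), as printed, is off by three orders
of magnitude on the same ensembles (λ_j ≈ 10–20 while CM steps are ~0.02)
and is therefore exposed but not asserted; likewise the β_j series
correlates with P(t1−t0;tj+1−tj) only up to sign and scale. α is the
least-squares scale between the exact and approximate series (closed
form), reported with the Euclidean fit distance.

The focal point minimizes the across-time dispersion of whole-CM-scaled
correlation curves over groups; a dispersion profile whose range is below
5% of its median is reported as no-FP (parallel curves). Ensemble-size
scans sample without replacement (sorted index sets, so the full-size
sample is literally the whole ensemble and its SD is exactly zero) and
report an empirical log-log scaling exponent of the repeat SD rather than
asserting a particular power, because the expected exponent is itself in
question. Between-state sampling correlates per-state CM change series
over time; its convergence diagnostic is the Euclidean distance between
standardized correlation-contribution curves at consecutive sizes.

## Barcodes

A barcode is a maximal run of chromosomally consecutive genes sharing one
critical state; its correlation length is end(last) − start(first) in bp.
Runs close when the state changes; in windowed mode the final run of each
chromosome is flagged truncated (its right end is unobserved), which
reconciles plain run-length encoding with the worked example in which
..S-S-S-T-T-S.. yields two complete barcodes and a truncated tail. Whole-
chromosome inputs never truncate.

Barcode expression defaults to the arithmetic mean of member ln ε — equal
member weighting, so a domain is represented by its typical member. The
alternative (mean of linear ε, `aggregate='mean_linear'`) lets the single
highest-expressed member dominate a unit; under the randomization null
below this reconstructs single-gene behavior inside mixed pseudo-barcodes
and hides the state-mixing effect, which is why it is not the default.

Random-barcode I resamples existing barcodes across states and averages
the correlation series. Random-barcode II picks random unused positions
and joins each with 1–4 unused right neighbors (states ignored), default
3130 pseudo-barcodes. The source description — "the number of elements is
assigned randomly from 1 to 4 neighboring genes" — is ambiguous between
run lengths {1..4} and a selected gene plus 1–4 neighbors; the package
adopts the latter. The deciding observation: the gene-level sandpile
transition is itself sharp, so a null containing a ~25% fraction of raw
single-gene units (the {1..4} reading) retains about 60% of the structured
singularity and could never appear flat, whereas all-mixed units reproduce
the documented near-total loss of the transition. Requesting pseudo-
barcodes far beyond the available gene pool reintroduces fragment
singletons at exhaustion; the default count uses roughly a third of the
genes, as in the original configuration.

## Synthetic data generator

The generator is the package's study stand-in; its defaults are the
conditions all recovery tests run under.

Causal structure: genes are organized in chromosomal runs (geometric
lengths, means 1.3 / 2.0 / 2.5 genes for super / near / sub; successive
runs differ in state, so planted runs are maximal). Each run carries a
stratum, a target-fluctuation center, an expression context, and — in the
sub stratum — a high- or low-expression component (HES/LES, equal weight).
This run-level coherence is the chromatin-domain picture in which the
domain, not the gene, is the dynamical unit; it is what the state-mixing
null destroys.

Per gene: target nrmsf ν_i is the run center plus member jitter, reflected
into the stratum range — reflection rather than clipping, because the
stratum edges coincide with partition thresholds and an atom exactly at a
threshold would make labels float-rounding-dependent. One super gene is
pinned to ν = 1, which anchors the genome-wide normalization. Mean
expression follows the planted power law ε̄ = (α/(1−ν))^{1/β} (defaults
α = 1.27, β = 0.16), plateaued above ν = 0.5 because the law has no
bounded mean as ν → 1; run- and member-level lognormal factors (mean one
on the linear scale, so group averages stay on the law) provide the
scatter, and the sub-stratum HES/LES factors (1.65 / 0.35, mean one)
create the bimodal marginal.

Dynamics: ε_i(t_j) = ε̄_i + ν_i R z_i(t_j) with R = 2.64 the target
maximum rmsf. The pattern z mixes a stratum waveform (sinusoid over the
sample index with period 8 samples — the sampling grid is log-like in
time, so oscillation is modeled per observation; a square-wave option
exists), run-coherent noise (half the stochastic variance) and gene-level
white noise, then is standardized per gene to zero mean and unit
population SD. Standardization makes the realized rmsf exactly ν_i R, so
the empirical nrmsf equals the planted target and state recovery is exact
by construction — the tests then verify the analysis pipeline, not the
generator's luck. The sub-stratum LES component oscillates (variance
fraction 0.6) in anti-phase to the super stratum (fraction 0.7, phase π);
the near stratum is nearly flat (0.05). Oscillation only in the swinging
low-expression component is what couples the correlation series to the CM
motion. Infeasible settings (fluctuation amplitudes that would drive
linear expression nonpositive) raise immediately with a diagnostic.

Annotation: genes are laid down in run order across 6 chromosomes,
lognormal gene lengths (median 27 kbp, σ_ln = 0.8 — protein-coding-like)
and gaps (median 5 kbp), non-overlapping.

What the generator does **not** emulate: measurement noise of a specific
platform, probe-level effects and probe multiplicity, missing data,
replicate structure, heavy-tailed expression noise (a square-wave switch
exists but tails are Gaussian), distance-dependent decay of domain
coherence, and any real chromosomal landmark structure. Tests passing on
this generator show the pipeline recovers the structure the model class
assumes; they do not certify detection power on data whose fluctuation
strata are weaker, unclustered, or confounded with batch effects.

## Problem sizes and determinism

Default study conditions are 20 000 genes × 18 time points (the original
grid, 0–72 h). The test suite and the acceptance script run the full
pipeline at this size (seconds per stage); ensemble scans use 50–400
repeats and the between-state sampler 200 repeats of m = 100. Every
stochastic operation takes an explicit seed (`numpy.random.default_rng`);
identical seeds give bit-identical synthetic data and reports.

## Known limitations

* The CP localization (apex-in-window with maximal prominence) and the
  divergence-onset rule (first group whose between-time DEAB spread
  exceeds twice the median, within ±2 groups of the CP) are
  operationalizations of criteria the source material applies visually.
* On the default generator the sandpile apex sits at ⟨nrmsf⟩ ≈ 0.21 —
  above the modality boundary (≈ 0.08) — because the plateaued power law
  concentrates high-expression static genes at high ν; the two
  transitions are distinct in this synthetic world, and the pipeline's
  confirmations treat them as separate checks.
* Eq-4/Eq-5 forms of the CM algebra are reported, not asserted (see
  above); only the Eq-2/Eq-3 forms verify quantitatively.
* `detect_focal_point` reports the dispersion minimum; on the default
  generator this lands in the super-critical range rather than at the CP,
  so FP–CP coincidence is a property of real data to be tested, not a
  generator guarantee.
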
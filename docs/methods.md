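# Methods

## The estimation problem

The population recombination rate ρ = 4·Ne·r measures how often a window
of sequence recombines per generation, scaled by the effective population
size. It leaves a statistical footprint in phased polymorphism data —
more recombination means more distinct haplotypes, weaker linkage
disequilibrium, and less variance in pairwise differences — but
likelihood-based estimators that read this footprint (full-likelihood or
two-locus composite likelihood) are far too slow for genome scans on
modern sample sizes. `eprr` instead *learns* the inverse mapping from
summary statistics to ρ on simulated data, window by window.

## Model and pipeline

A window is an n × S matrix of phased haplotypes at segregating sites.
The pipeline for one window:

1. **Compact folded spectrum.** Each column's folded minor-allele class
   is computed (multi-allelic sites use n minus the count of the most
   frequent allele; columns with missing cells fold on the non-missing
   sample size). The window's conditioning context is (ξ2′, ξx′), the
   numbers of folded-doubleton and pooled 3..n−3 sites. Folded singletons
   ξ1′ carry almost no recombination information and are excluded from
   everything downstream. n ≥ 6 is required for the three classes to be
   distinct.
2. **Summary statistics.** On the singleton-stripped matrix: Sk²
   (population variance of pairwise sequence differences over all
   haplotype pairs), mean r² over all SNP pairs (complete cases per
   pair), haplotype heterozygosity 1 − Σp², and the number of distinct
   haplotypes H ("?" counts as a fifth symbol).
3. **Conditional training.** For each ρ on the grid
   {0, 0.5, 1, 2, 5, 10, 20, 40, 70, 110, 170}, 100 replicate datasets
   are simulated *conditional on the observed (ξ2′, ξx′)* and summarized.
   A component-wise boosted additive model ρ = f(SS) is fitted (see
   below).
4. **Prediction and grid extension.** ρ̂ = f(SSobs), floored at 0. If the
   observed H exceeds Hthres — the 95th percentile of H among training
   replicates at the top grid ρ — the true ρ likely lies beyond the grid;
   training is extended to {…, 180, 190, 200, 220, 250, 300, 350}, the
   model refitted (Hthres recomputed at ρ = 350) and the window
   re-predicted.
5. **Linear correction.** B = 100 datasets are simulated at ρ = ρ̂ under
   the same conditioning and re-estimated, giving ρ̂s. The factor
   α = ρ̂ / mean(ρ̂s) removes multiplicative bias of the pipeline around
   ρ̂; the estimate is α·ρ̂, with the 2.5/97.5 percentiles of α·ρ̂s as a
   simple interval. Below ε = 10⁻³ the division is skipped and the
   estimate flagged uncorrected; the correction preserves 0 and never
   changes sign.

## Coalescent scaling

Time is scaled so that one pair of lineages coalesces at rate 1
(E[TMRCA] = 1 for n = 2); the window is the unit interval; each lineage
recombines at rate ρ/2; mutations fall at rate θ/2 per unit of total
branch length, so E[S] = θ·Σ 1/i and E[π] = θ. Genealogies come from
msprime (haploid samples, population size 1, recombination rate ρ/2 over
unit length); mutation dropping is implemented here:

- **Fixed-θ**: Poisson(θ/2 × branch-length area) mutations, each on a
  tree chosen proportional to span × length, branch proportional to
  length.
- **Fixed-S**: exactly S mutations; position uniform, branch proportional
  to length in the marginal tree there. (Note that conditioning on S
  tilts ratio statistics: E[ξ1/S] = E[L_ext/L_tot] ≠ 1/a_n.)
- **Spectrum-conditional**: one mutation per requested column; the
  position is uniform, and the branch is drawn proportional to length
  among branches whose folded subtree class matches the column's target
  class; positions with no admissible branch are redrawn. This is exact
  length-proportional placement conditioned on class membership; the
  genealogy itself is *not* conditioned on the spectrum (the information
  in ξ1′ and in the joint site pattern about tree shape is deliberately
  ignored, as in the method's design).

When the observed window has missing cells, every training column is
drawn so that its folded class *after masking the observed column's
missing rows* matches; training data thus carry the exact observed
missing pattern. Under the finite-site model, class-placed mutations are
projected onto L discrete sites (uniform site per mutation, successive
hits switching carriers to a uniformly chosen different nucleotide) and
the realized post-projection spectrum is repaired by adding/removing
mutations until it matches the observation — conditioning on the scale
actually measured. Missing-data and finite-site conditioning are not
combined.

## The regression engine

`gamboost`-style component-wise L2 boosting, written against numpy/scipy:
cubic P-spline base learners (20 equal-width segments, second-difference
penalty, λ calibrated by bisection to 4 effective degrees of freedom per
learner), squared-error loss, learning rate ν = 0.1, 250 iterations, no
early stopping. At each iteration the base learner with the smallest
residual sum of squares is updated. Predictors are clamped to their
training range (constant extrapolation); degenerate (constant) predictors
are skipped. The fit is deterministic and invariant to training-row
order. Holdout calibration is flat in the iteration count well past 250,
so the default is not a sensitive knob.

## Model cache and training-tree pool

Genome scans estimate thousands of windows but only one model per unique
(n, ξ2′, ξx′, missing-pattern, finite-site length, grid) context; models
are cached in memory and optionally on disk. Two further economies:

- Training genealogies are pooled per (n, ρ, demography) and shared
  across conditioning contexts; mutation placement is redrawn per
  replicate, so each model's training set is a proper conditional sample.
  Models trained from the shared pool are mildly correlated with each
  other, which leaves each individual estimate unbiased. Correction
  simulations at ρ̂ always draw fresh genealogies.
- Extending the grid reuses the base-grid training rows (per-ρ seeds are
  grid-independent), adding only the seven new grid values.

## Genome scanning

Windows (default 50 kb, step = window for plain maps, window/2 for
variable-rate maps) are anchored at multiples of the step from position
0; a final partial window is dropped. Site filters: SNPs only, QUAL ≥ 20.
Window filters: no overlap with assembly gaps; ξ2′ + ξx′ ≥ 10. VCF
positions convert to 0-based half-open coordinates; unphased or missing
genotype cells become "?". Ne is calibrated as Σρ over windows divided by
4× the genetic length (Morgans) of the same intervals under a reference
pedigree map, and ρ converts to cM/Mb as 100·ρ_per_Mb/(4Ne). Map
comparison rebins window sums (length-weighted) to a common scale and
reports Pearson correlation over bins untouched by skipped windows.

For variable rates within windows, overlapping estimates (step =
window/2) are decomposed into half-window rates x_i by nonnegative least
squares on ρ_k = x_k + x_{k+1} per 3-window system; the least-squares
minimizer set is a segment along (1,−1,1,−1), on which the product
x1·x2·x3·x4 (the stated tie-break, a proxy for entropy) is maximized in
closed form via the quartic's stationary points. When the product is zero
on the whole segment the midpoint is taken. Each half-window's final rate
averages all systems covering it; skipped windows split the track and
runs shorter than three windows are left undecomposed.

## What the simulations do and do not emulate

The built-in generator produces phased, error-free haplotypes under the
standard neutral coalescent (optionally a bottleneck or exponential
growth, and optionally masked cells or finite-site multiple hits). It
does not emulate genotyping or phasing error, gene conversion, selection,
population structure, or rate variation *within* a simulated window.
Passing validation therefore certifies the statistical machinery under
the stated models, not robustness to everything real data can do.

## Validation scale and known behavior

Replicate counts in the test suite and acceptance script were fixed from
single-core timing of the simulator (a full model build is ~2–4 s): the
acceptance script runs 50 replicates per design point with the method
defaults (100 training replicates per grid ρ, B = 100); the test suite
runs 20–50 replicates per condition with 50 training replicates where the
pilot behavior is insensitive to that choice. Acceptance bands are always
three standard errors with SE = SD/√(replicates run), using the reference
SD where one is known and the empirical SD otherwise.

Known behavior worth stating plainly:

- At true ρ = 0 the estimate is nonnegative by construction, so its mean
  is strictly positive (≈1–1.6 at n = 100, S = 52).
- At low ρ with smaller samples (n = 50) the mean estimate runs ~2 units
  low at ρ = 10. The conditional simulator matches observed data closely
  in the marginal summary statistics but ignores what ξ1′ and the joint
  site pattern say about tree shape, a mismatch the linear correction
  (which is self-consistent by construction) cannot remove. The same
  mechanism is much weaker at n = 100.
- Under fixed θ the low-ρ mean is sensitive to training-set size (100
  replicates per grid ρ gives ≈9.0 at ρ = 10; 50 gives ≈7.9), so θ-mode
  validation uses the full 100.
- Grid extension is a ~1% per-window event at ρ = 150 (well inside the
  grid); it engages almost surely for data beyond the grid top (11/12
  windows at ρ = 300), which is what validation certifies.
- Under a strong recent bottleneck (t0 = 0.001, t1 = 0.01, N0/N1 = 100)
  estimates collapse far below 4·N0·r, the expected direction: training
  assumes the standard neutral model while the data carry bottleneck
  genealogies.

## Numerical choices

- Seeds: one root seed; every operation derives an independent stream
  from (root, tag, indices) via blake2b, so any replicate reproduces in
  isolation and msprime seeds stay below 2³¹.
- Conditional placement retries a fresh position when a tree lacks the
  required class (cap 1000 sweeps), then falls back to fresh genealogies.
- ε = 10⁻³ guards the α division; B < 2 is rejected.
- Windows with fewer than 2 usable sites (mean r² undefined) are skipped,
  never imputed.
- Ties in the boosting base-learner selection break toward the
  first-listed statistic (deterministic).
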
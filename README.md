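# eprr — fast estimation of population recombination rates

`eprr` estimates the population recombination rate ρ = 4·Ne·r from phased
intraspecific polymorphism data, window by window, fast enough for
genome-wide scans on a single core. It is aimed at population geneticists
who need genetic maps or hotspot scans from population resequencing data
(phased VCF) and at simulation studies of recombination-rate inference.

## How it works

Instead of evaluating a likelihood, `eprr` learns the inverse mapping
from data summaries to ρ:

1. A window of n phased haplotypes is reduced to its compact folded
   mutation frequency spectrum {ξ1′, ξ2′, ξx′} (folded singletons ξ1′
   are discarded — they carry almost no recombination signal) and four
   statistics **SS** = (Sk², mean r², haplotype heterozygosity, H).
2. Coalescent simulations *conditional on the observed (ξ2′, ξx′)* are
   generated over a training grid ρ ∈ {0, 0.5, 1, 2, 5, 10, 20, 40, 70,
   110, 170} (100 replicates each) and a boosted additive regression
   ρ = f(SS) is fitted (component-wise boosting with P-spline base
   learners).
3. ρ̂ = f(SSobs). If the observed haplotype count H exceeds Hthres (the
   95th percentile of H at the top training ρ), the grid is extended to
   350 and the model refitted.
4. A linear correction de-biases the prediction: B = 100 simulations at
   ρ̂ give re-estimates ρ̂s, α = ρ̂ / mean(ρ̂s), and the reported
   estimate is α·ρ̂.

Genome scans batch windows by (ξ2′, ξx′) so each unique combination
trains one model; maps can be calibrated to an effective population size
Ne against a pedigree-based genetic map and converted to cM/Mb via
r = 100·ρ/(4Ne). For rate variation below the window scale, overlapping
windows (step = window/2) are decomposed into half-window rates by
nonnegative least squares with a product tie-break.

## Worked example

```python
from eprr import (SimContext, simulate_trees, drop_mutations_fixed_S,
                  ModelCache, EstimateOptions, estimate_window)

ts = simulate_trees(SimContext(n=100, rho=50, seed=42))   # true rho = 50
window = drop_mutations_fixed_S(ts, S=52, seed=42)

cache = ModelCache(seed=1, training_reps=100)
est = estimate_window(window, EstimateOptions(seed=1, cache=cache))
print(est.rho_raw, est.alpha, est.rho)
```

prints (about ten seconds of training and correction on one core):

```
59.99757048042117 0.8801565797244779 52.8072564258258
```

i.e. the raw regression prediction is ρ̂ ≈ 60.0, the correction factor
α ≈ 0.880, and the corrected estimate ≈ 52.8 — one draw from a sampling
distribution centred on the truth (over replicate windows at ρ = 50 the
mean estimate is ≈ 49.8 with SD ≈ 12). The `examples/` directory has
narrative scripts for each capability: simulating and summarizing
windows, single-window estimation, variable-rate decomposition, and a
small VCF genome scan; each prints what the numbers mean.

A thin CLI mirrors the library: `eprr simulate`, `eprr estimate`,
`eprr scan`, `eprr decompose`, `eprr calibrate`, `eprr compare`.

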
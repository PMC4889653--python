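"""Simulate one haplotype window and summarize it.

Draws genealogies for n = 50 chromosomes with recombination rate
rho = 4Ner = 20 across the window, drops S = 45 mutations, and prints the
compact folded mutation frequency spectrum and the four summary
statistics the estimator regresses on.
"""

from eprr import (
    SimContext,
    drop_mutations_fixed_S,
    fold_spectrum,
    simulate_trees,
    summarize,
)

ts = simulate_trees(SimContext(n=50, rho=20, seed=42))
print(f"marginal trees along the window: {ts.num_trees}")

m = drop_mutations_fixed_S(ts, S=45, seed=42)
spec = fold_spectrum(m)
print(f"folded spectrum: xi1'={spec.xi1p} xi2'={spec.xi2p} xix'={spec.xixp}")

ss = summarize(m)  # folded singletons are excluded here
print(f"Sk^2 (variance of pairwise differences) = {ss.sk2:.3f}")
print(f"mean r^2 over SNP pairs               = {ss.mean_r2:.4f}")
print(f"haplotype heterozygosity              = {ss.hap_het:.4f}")
print(f"distinct haplotypes H                 = {ss.H}")
print()
print("Higher rho shuffles variation across haplotypes: H and Sk^2 are the")
print("most recombination-sensitive of the four; the regression uses all.")
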
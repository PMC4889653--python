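import numpy as np
import pytest
from scipy import stats

from eprr.coalsim import (
    DemographyModel,
    SimContext,
    drop_mutations_conditional,
    drop_mutations_conditional_finite,
    drop_mutations_fixed_S,
    drop_mutations_theta,
    finite_site_project,
    mask_missing,
    multiple_hit_probability,
    simulate_trees,
)
from eprr.haplotype import MISSING
from eprr.sumstats import fold_spectrum


def test_context_validation():
    with pytest.raises(ValueError):
        SimContext(n=1, rho=0)
    with pytest.raises(ValueError):
        SimContext(n=10, rho=-1)
    with pytest.raises(ValueError):
        DemographyModel("weird")


def test_no_recombination_gives_single_tree():
    ts = simulate_trees(SimContext(n=10, rho=0, seed=5))
    assert ts.num_trees == 1


def test_pairwise_tmrca_expectation():
    # E[TMRCA] = 1 for n=2 under the pair-coalescence time scaling
    heights = []
    for k in range(2000):
        ts = simulate_trees(SimContext(n=2, rho=0, seed=k + 1))
        heights.append(ts.first().time(ts.first().root))
    mean = np.mean(heights)
    se = np.std(heights) / np.sqrt(len(heights))
    assert abs(mean - 1.0) < 3 * se


def test_tree_count_increases_with_rho():
    counts = {}
    for rho in (0, 5, 50):
        counts[rho] = np.mean(
            [simulate_trees(SimContext(n=10, rho=rho, seed=k + 1)).num_trees
             for k in range(200)]
        )
    assert counts[0] == 1.0
    assert counts[0] < counts[5] < counts[50]


def test_determinism_byte_for_byte():
    ts1 = simulate_trees(SimContext(n=12, rho=8, seed=99))
    ts2 = simulate_trees(SimContext(n=12, rho=8, seed=99))
    m1 = drop_mutations_conditional(ts1, 3, 7, seed=4)
    m2 = drop_mutations_conditional(ts2, 3, 7, seed=4)
    assert m1 == m2
    assert m1.alleles.tobytes() == m2.alleles.tobytes()


@pytest.mark.parametrize("n,xi2p,xixp", [(10, 3, 7), (6, 1, 1), (100, 5, 47)])
def test_conditional_spectrum_exact(n, xi2p, xixp):
    ts = simulate_trees(SimContext(n=n, rho=10, seed=n))
    m = drop_mutations_conditional(ts, xi2p, xixp, seed=2)
    assert m.S == xi2p + xixp
    spec = fold_spectrum(m)
    assert (spec.xi1p, spec.xi2p, spec.xixp) == (0, xi2p, xixp)
    assert np.all(np.diff(m.positions) > 0)


def test_conditional_n6_x_class_is_three():
    ts = simulate_trees(SimContext(n=6, rho=0, seed=8))
    m = drop_mutations_conditional(ts, 1, 1, seed=3)
    assert sorted(m.folded_counts()) == [2, 3]


def test_conditional_rejects_empty_request():
    ts = simulate_trees(SimContext(n=10, rho=0, seed=1))
    with pytest.raises(ValueError):
        drop_mutations_conditional(ts, 0, 0, seed=1)


def test_conditional_with_missing_pattern_matches_post_mask():
    ts = simulate_trees(SimContext(n=20, rho=5, seed=31))
    rng = np.random.default_rng(7)
    column_missing = [rng.choice(20, size=rng.integers(0, 8), replace=False)
                      for _ in range(10)]
    m = drop_mutations_conditional(ts, 4, 6, seed=9, column_missing=column_missing)
    spec = fold_spectrum(m)  # folds on the non-missing sample size
    assert (spec.xi2p, spec.xixp) == (4, 6)


def test_fixed_s_shapes():
    ts = simulate_trees(SimContext(n=100, rho=10, seed=2))
    assert drop_mutations_fixed_S(ts, 52, seed=1).S == 52
    ts2 = simulate_trees(SimContext(n=2, rho=0, seed=2))
    m = drop_mutations_fixed_S(ts2, 1, seed=1)
    assert m.S == 1 and sorted(m.alleles[:, 0]) == [0, 1]


def test_fixed_s_singleton_fraction():
    # with S fixed per replicate, E[xi_1 / S] equals the expected external
    # branch-length fraction E[L_ext / L_tot] (not 1/a_n, the unconditional
    # SFS ratio): check placement against that per-tree closed form on the
    # same genealogies.  The naive 1/a_n = 0.282 here, the true value ~0.30.
    n, S, reps = 20, 20, 1500
    diffs = []
    for k in range(reps):
        ts = simulate_trees(SimContext(n=n, rho=0, seed=k + 1))
        tree = ts.first()
        ext = sum(tree.branch_length(u) for u in ts.samples())
        frac_tree = ext / tree.total_branch_length
        m = drop_mutations_fixed_S(ts, S, seed=k + 1)
        derived = m.alleles.sum(axis=0)
        diffs.append(np.mean(derived == 1) - frac_tree)
    mean = np.mean(diffs)
    se = np.std(diffs) / np.sqrt(reps)
    assert abs(mean) < 3 * max(se, 1e-4)


def test_neutral_sfs_chi_square():
    # fixed-theta dropping reproduces E[xi_i] proportional to 1/i
    n, reps = 8, 2000
    counts = np.zeros(n - 1)
    for k in range(reps):
        ts = simulate_trees(SimContext(n=n, rho=0, seed=k + 1))
        m = drop_mutations_theta(ts, 3.0, seed=k + 1)
        if m.S:
            derived = m.alleles.sum(axis=0)
            for i in range(1, n):
                counts[i - 1] += np.sum(derived == i)
    expected = (1.0 / np.arange(1, n))
    expected = expected / expected.sum() * counts.sum()
    chi2 = stats.chisquare(counts, expected)
    assert chi2.pvalue > 1e-3


def test_theta_watterson_mean_s():
    n, theta, reps = 100, 10.0, 300
    a = np.sum(1.0 / np.arange(1, n))
    s_vals = []
    for k in range(reps):
        ts = simulate_trees(SimContext(n=n, rho=10, seed=k + 1))
        s_vals.append(drop_mutations_theta(ts, theta, seed=k + 1).S)
    mean, se = np.mean(s_vals), np.std(s_vals) / np.sqrt(reps)
    assert abs(mean - theta * a) < 3 * se


def test_theta_pairwise_diversity():
    reps, theta = 2000, 2.0
    pis = []
    for k in range(reps):
        ts = simulate_trees(SimContext(n=2, rho=0, seed=k + 1))
        m = drop_mutations_theta(ts, theta, seed=k + 1)
        pis.append(np.sum(m.alleles[0] != m.alleles[1]))
    mean, se = np.mean(pis), np.std(pis) / np.sqrt(reps)
    assert abs(mean - theta) < 3 * se


def test_multiple_hit_probability_values():
    assert round(multiple_hit_probability(52, 10000), 2) == 0.12
    assert multiple_hit_probability(1, 150) == 0.0
    assert multiple_hit_probability(60, 50) == 1.0
    # Monte-Carlo cross-check of the birthday product
    rng = np.random.default_rng(0)
    draws = rng.integers(0, 20, size=(100_000, 5))
    mc = np.mean([len(set(row)) < 5 for row in draws])
    assert abs(multiple_hit_probability(5, 20) - mc) < 0.01


def test_finite_site_projection():
    ts = simulate_trees(SimContext(n=10, rho=0, seed=3))
    m1 = drop_mutations_fixed_S(ts, 1, seed=1)
    out = finite_site_project(m1, 10_000, seed=5)
    assert out.S == 1  # single mutation never collides
    m2 = drop_mutations_fixed_S(ts, 2, seed=2)
    out2 = finite_site_project(m2, 1, seed=5)
    assert np.all(out2.positions == 1)  # both mutations hit site 1
    assert out2.S <= 1


def test_finite_site_collision_rate():
    # with 52 mutations on 10 kb, ~12% of replicates lose >= 1 site
    ts = simulate_trees(SimContext(n=20, rho=0, seed=11))
    m = drop_mutations_fixed_S(ts, 52, seed=11)
    reps = 400
    collided = [finite_site_project(m, 10_000, seed=k).S < 52 for k in range(reps)]
    frac = np.mean(collided)
    p = multiple_hit_probability(52, 10_000)
    se = np.sqrt(p * (1 - p) / reps)
    assert abs(frac - p) < 4 * se


def test_conditional_finite_spectrum_matches():
    ts = simulate_trees(SimContext(n=100, rho=50, seed=21))
    m = drop_mutations_conditional_finite(ts, 3, 30, 150, seed=6)
    c = m.folded_counts()
    assert int(np.sum(c == 2)) == 3
    assert int(np.sum(c >= 3)) == 30


def test_mask_missing_counts_and_identity():
    ts = simulate_trees(SimContext(n=10, rho=0, seed=13))
    m = drop_mutations_fixed_S(ts, 10, seed=13)
    assert mask_missing(m, 0, seed=1) == m
    masked = mask_missing(m, 30, seed=1)
    assert len(masked.meta["mask_pattern"]) == 30  # round(0.3 * 10 * 10)
    assert mask_missing(m, 100, seed=1).S == 0


def test_bottleneck_reduces_tree_height():
    dem = DemographyModel("bottleneck", t0=0.001, t1=0.01, size_ratio=100)
    h_con, h_bot = [], []
    for k in range(200):
        t_c = simulate_trees(SimContext(n=20, rho=0, seed=k + 1))
        t_b = simulate_trees(SimContext(n=20, rho=0, demography=dem, seed=k + 1))
        h_con.append(t_c.first().time(t_c.first().root))
        h_bot.append(t_b.first().time(t_b.first().root))
    assert np.mean(h_bot) < np.mean(h_con)
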
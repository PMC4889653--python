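"""Coalescent-with-recombination simulation of haplotype windows.

Tree genealogies come from msprime; mutation dropping is done here because
the estimator needs samples drawn *conditional* on the compact folded
mutation frequency spectrum (xi2', xix'), a scheme no off-the-shelf
mutation model provides.

Scaling conventions (Hudson's ms): time is scaled so that a pair of
lineages coalesces at rate 1 (E[TMRCA] = 1 for n = 2), the window is the
unit interval, rho = 4*Ne*r is the total scaled recombination rate of the
window (each lineage recombines at rate rho/2), and mutations fall at rate
theta/2 per unit of total branch length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import msprime
import numpy as np
import tskit
from numba import njit

from ._rng import derive_seed, generator
from .haplotype import MISSING, HaplotypeMatrix

__all__ = [
    "SimContext",
    "DemographyModel",
    "PlacementError",
    "simulate_trees",
    "drop_mutations_conditional",
    "drop_mutations_conditional_finite",
    "drop_mutations_fixed_S",
    "drop_mutations_theta",
    "finite_site_project",
    "multiple_hit_probability",
    "mask_missing",
]

_NUCLEOTIDES = np.array([2, 3, 4, 5], dtype=np.uint8)  # codes for A, C, G, T


class PlacementError(RuntimeError):
    """No branch of the required frequency class could be found."""


@dataclass(frozen=True)
class DemographyModel:
    """Single-population size history.

    kind
        ``constant``, ``bottleneck`` or ``exponential_growth``.
    t0
        Bottleneck: time (in scaled units, looking backwards) at which the
        bottleneck ended.  Unused for growth.
    t1
        Bottleneck: duration of the bottleneck.  Growth: time at which the
        expansion started.
    size_ratio
        N0/N1, present size over bottleneck/ancestral size.
    """

    kind: str = "constant"
    t0: float = 0.0
    t1: float = 0.0
    size_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "bottleneck", "exponential_growth"):
            raise ValueError(f"unknown demography kind: {self.kind!r}")
        if self.t0 < 0 or self.t1 < 0 or self.size_ratio <= 0:
            raise ValueError("demography times must be >= 0 and size_ratio > 0")

    def to_msprime(self) -> msprime.Demography:
        dem = msprime.Demography()
        dem.add_population(initial_size=1.0)
        if self.kind == "bottleneck":
            dem.add_population_parameters_change(
                time=self.t0, initial_size=1.0 / self.size_ratio
            )
            dem.add_population_parameters_change(time=self.t0 + self.t1, initial_size=1.0)
        elif self.kind == "exponential_growth":
            alpha = math.log(self.size_ratio) / self.t1
            dem.add_population_parameters_change(time=0.0, growth_rate=alpha)
            dem.add_population_parameters_change(
                time=self.t1, initial_size=1.0 / self.size_ratio, growth_rate=0.0
            )
        return dem


@dataclass(frozen=True)
class SimContext:
    """Simulation parameters for one window.

    n is the number of sampled chromosomes; rho = 4*Ne*r is the scaled
    recombination rate of the whole window.
    """

    n: int
    rho: float
    demography: DemographyModel | None = None
    seed: int = 1

    def __post_init__(self) -> None:
        if int(self.n) != self.n or self.n < 2:
            raise ValueError("n must be an integer >= 2")
        if self.rho < 0:
            raise ValueError("rho must be >= 0")


def simulate_trees(ctx: SimContext, length_scale: float = 1.0) -> tskit.TreeSequence:
    """Realize an ancestral recombination graph for one window.

    Returns a tree sequence over ``[0, length_scale)`` whose marginal
    trees are the genealogies of the ctx.n sampled chromosomes.
    Deterministic given ``ctx.seed``.
    """
    if length_scale <= 0:
        raise ValueError("length_scale must be positive")
    dem = (ctx.demography or DemographyModel()).to_msprime()
    return msprime.sim_ancestry(
        samples=ctx.n,
        ploidy=1,
        demography=dem,
        sequence_length=length_scale,
        recombination_rate=ctx.rho / 2.0 / length_scale,
        discrete_genome=False,
        random_seed=derive_seed(ctx.seed, "ancestry"),
    )


# ---------------------------------------------------------------------
# per-tree bookkeeping
# ---------------------------------------------------------------------

@njit
def _subtree_counts(postorder, parent, flags, out):
    # accumulate, in postorder, the number of flagged samples below each node
    for i in range(postorder.shape[0]):
        u = postorder[i]
        out[u] += flags[u]
        p = parent[u]
        if p != -1:
            out[p] += out[u]


class _TreeData:
    """Branch lengths and subtree sample counts for one marginal tree."""

    def __init__(self, tree: tskit.Tree, times: np.ndarray, sample_flags: np.ndarray):
        self.tree = tree
        post = tree.postorder()
        parent = tree.parent_array
        counts = np.zeros(parent.shape[0], dtype=np.int64)
        _subtree_counts(post, parent, sample_flags.astype(np.int64), counts)
        par = parent[post]
        bl = np.where(par != -1, times[par] - times[post], 0.0)
        self.nodes = post
        self.branch_lengths = bl
        self.sizes = counts[post]

    def masked_sizes(self, mask_flags: np.ndarray) -> np.ndarray:
        counts = np.zeros(self.tree.parent_array.shape[0], dtype=np.int64)
        _subtree_counts(self.nodes, self.tree.parent_array, mask_flags.astype(np.int64), counts)
        return counts[self.nodes]

    def samples_under(self, node: int, k: int) -> np.ndarray:
        return np.fromiter(self.tree.samples(node), dtype=np.int64, count=k)


class _TreeCache:
    """Lazy per-position access to _TreeData over a tree sequence."""

    def __init__(self, ts: tskit.TreeSequence):
        self.ts = ts
        self.times = ts.nodes_time
        self.sample_flags = np.zeros(ts.num_nodes, dtype=np.int64)
        self.sample_flags[ts.samples()] = 1
        self.breakpoints = ts.breakpoints(as_array=True)
        self._cache: dict[int, _TreeData] = {}

    def at(self, pos: float) -> _TreeData:
        idx = int(np.searchsorted(self.breakpoints, pos, side="right") - 1)
        td = self._cache.get(idx)
        if td is None:
            td = _TreeData(self.ts.at(pos), self.times, self.sample_flags)
            self._cache[idx] = td
        return td


# ---------------------------------------------------------------------
# mutation dropping
# ---------------------------------------------------------------------

def _build_matrix(
    n: int,
    columns: list[np.ndarray],
    positions: list[float],
    missing: list[np.ndarray] | None = None,
) -> HaplotypeMatrix:
    order = np.argsort(positions, kind="stable")
    alleles = np.zeros((n, len(columns)), dtype=np.uint8)
    pos = np.empty(len(columns), dtype=float)
    for out_j, j in enumerate(order):
        alleles[columns[j], out_j] = 1
        if missing is not None and missing[j] is not None and len(missing[j]):
            alleles[missing[j], out_j] = MISSING
        pos[out_j] = positions[j]
    return HaplotypeMatrix(alleles, pos)


def _place_class_columns(
    ts: tskit.TreeSequence,
    targets: Sequence[int],
    rng: np.random.Generator,
    column_missing: Sequence[np.ndarray] | None = None,
    max_retries: int = 1000,
) -> tuple[list[np.ndarray], list[float], list[np.ndarray]]:
    """Sample one mutation per target class; see drop_mutations_conditional.

    Positions are drawn up front and resolved in a single forward sweep
    over the marginal trees; sites whose tree has no admissible branch
    redraw their position and are resolved in a further sweep.
    """
    n = ts.num_samples
    L = ts.sequence_length
    k = len(targets)
    times = ts.nodes_time
    sflags = np.zeros(ts.num_nodes, dtype=np.int64)
    sflags[ts.samples()] = 1

    miss: list[np.ndarray] = []
    mask_flags: list[np.ndarray | None] = []
    for j in range(k):
        rows = (
            np.asarray(column_missing[j], dtype=np.int64)
            if column_missing is not None
            else np.empty(0, dtype=np.int64)
        )
        if n - rows.size < 6:
            raise ValueError("a column's non-missing sample size must be >= 6")
        miss.append(rows)
        if rows.size:
            f = np.zeros(ts.num_nodes, dtype=np.int64)
            f[rows] = 1
            mask_flags.append(f)
        else:
            mask_flags.append(None)

    pos = rng.uniform(0, L, size=k)
    derived: list[np.ndarray | None] = [None] * k
    pending = list(range(k))

    for _sweep in range(max_retries):
        if not pending:
            break
        plist = sorted(pending, key=lambda j: pos[j])
        still: list[int] = []
        pi = 0
        for tree in ts.trees():
            right = tree.interval.right
            post = parent = bl = sizes = counts = None
            while pi < len(plist) and pos[plist[pi]] < right:
                j = plist[pi]
                pi += 1
                if post is None:
                    post = tree.postorder()
                    parent = tree.parent_array
                    counts = np.zeros(ts.num_nodes, dtype=np.int64)
                    _subtree_counts(post, parent, sflags, counts)
                    par = parent[post]
                    bl = np.where(par != -1, times[par] - times[post], 0.0)
                    sizes = counts[post]
                if mask_flags[j] is not None:
                    mcounts = np.zeros(ts.num_nodes, dtype=np.int64)
                    _subtree_counts(post, parent, mask_flags[j], mcounts)
                    eff = sizes - mcounts[post]
                    m_eff = n - miss[j].size
                else:
                    eff = sizes
                    m_eff = n
                folded = np.minimum(eff, m_eff - eff)
                ok = (folded == 2) if targets[j] == 2 else (folded >= 3)
                w = bl * ok
                tot = w.sum()
                if tot <= 0:
                    pos[j] = rng.uniform(0, L)  # redraw; resolve next sweep
                    still.append(j)
                    continue
                cw = np.cumsum(w)
                node_i = int(np.searchsorted(cw, rng.uniform(0, tot), side="right"))
                node_i = min(node_i, len(post) - 1)
                derived[j] = np.fromiter(
                    tree.samples(int(post[node_i])), np.int64, int(sizes[node_i])
                )
            if pi >= len(plist):
                break
        pending = still
    if pending:
        raise PlacementError(
            f"no admissible branch found for {len(pending)} site(s) "
            f"after {max_retries} sweeps"
        )
    return [d for d in derived], list(pos), miss


def drop_mutations_conditional(
    ts: tskit.TreeSequence,
    xi2p: int,
    xixp: int,
    seed: int,
    column_missing: Sequence[np.ndarray] | None = None,
    max_retries: int = 1000,
) -> HaplotypeMatrix:
    """Place mutations so the folded spectrum is exactly (0, xi2p, xixp).

    Each site draws a uniform position, takes the marginal tree there and
    samples a branch proportional to length among branches whose folded
    subtree class matches the site's target class (2 for the xi2' class,
    3..n-3 for the xix' class); positions with no admissible branch are
    redrawn.  Folded singletons are never produced.

    ``column_missing`` optionally gives, per requested column, the row
    indices to mark missing; the class of such a column is matched on the
    non-missing subsample, so the spectrum of the *observed* (masked)
    matrix equals the request exactly.
    """
    n = ts.num_samples
    if n < 6:
        raise ValueError("conditional placement requires n >= 6")
    xi2p, xixp = int(xi2p), int(xixp)
    if xi2p < 0 or xixp < 0 or xi2p + xixp < 1:
        raise ValueError("xi2p + xixp must be >= 1")
    total = xi2p + xixp
    if column_missing is not None and len(column_missing) != total:
        raise ValueError("column_missing must have one entry per requested column")

    rng = generator(seed, "conditional")
    targets = [2] * xi2p + [-1] * xixp  # -1 marks the pooled 3..n-3 class
    columns, positions, missing = _place_class_columns(
        ts, targets, rng, column_missing, max_retries
    )
    return _build_matrix(n, columns, positions, missing)


def drop_mutations_fixed_S(ts: tskit.TreeSequence, S: int, seed: int) -> HaplotypeMatrix:
    """Place exactly S mutations; branch chosen proportional to length at a
    uniformly drawn position."""
    if S < 1:
        raise ValueError("S must be >= 1")
    n = ts.num_samples
    rng = generator(seed, "fixed_S")
    cache = _TreeCache(ts)
    L = ts.sequence_length
    columns, positions = [], []
    for _ in range(int(S)):
        pos = float(rng.uniform(0, L))
        td = cache.at(pos)
        w = td.branch_lengths
        node_i = rng.choice(len(td.nodes), p=w / w.sum())
        derived = td.samples_under(int(td.nodes[node_i]), int(td.sizes[node_i]))
        columns.append(derived)
        positions.append(pos)
    return _build_matrix(n, columns, positions)


def drop_mutations_theta(ts: tskit.TreeSequence, theta: float, seed: int) -> HaplotypeMatrix:
    """Poisson(theta/2 x total branch length) mutations, infinite sites."""
    if theta <= 0:
        raise ValueError("theta must be > 0")
    n = ts.num_samples
    rng = generator(seed, "theta")
    spans, lengths, lefts = [], [], []
    for tree in ts.trees():
        spans.append(tree.span)
        lengths.append(tree.total_branch_length)
        lefts.append(tree.interval.left)
    spans = np.array(spans)
    lengths = np.array(lengths)
    area = float((spans * lengths).sum()) / ts.sequence_length
    total = rng.poisson(theta / 2.0 * area)
    if total == 0:
        return HaplotypeMatrix(np.zeros((n, 0), dtype=np.uint8), np.zeros(0))
    weights = spans * lengths
    per_tree = rng.multinomial(total, weights / weights.sum())
    cache = _TreeCache(ts)
    columns, positions = [], []
    for t_idx in np.flatnonzero(per_tree):
        for _ in range(per_tree[t_idx]):
            pos = float(rng.uniform(lefts[t_idx], lefts[t_idx] + spans[t_idx]))
            td = cache.at(pos)
            w = td.branch_lengths
            node_i = rng.choice(len(td.nodes), p=w / w.sum())
            derived = td.samples_under(int(td.nodes[node_i]), int(td.sizes[node_i]))
            columns.append(derived)
            positions.append(pos)
    return _build_matrix(n, columns, positions)


# ---------------------------------------------------------------------
# finite sites, missing data
# ---------------------------------------------------------------------

def _project_mutations(
    n: int,
    derived_sets: Sequence[np.ndarray],
    bps: Sequence[int],
    rng: np.random.Generator,
) -> HaplotypeMatrix:
    """Apply mutations at assigned discrete sites under the symmetric
    4-allele model; only segregating sites are kept."""
    order = rng.permutation(len(derived_sets))  # order in which multiple hits apply
    cols: dict[int, np.ndarray] = {}
    for j in order:
        bp = int(bps[j])
        state = cols.get(bp)
        if state is None:
            state = np.full(n, 2, dtype=np.uint8)  # ancestral 'A'
            cols[bp] = state
        carriers = np.asarray(derived_sets[j], dtype=np.int64)
        vals, counts = np.unique(state[carriers], return_counts=True)
        current = vals[np.argmax(counts)]
        choices = _NUCLEOTIDES[_NUCLEOTIDES != current]
        state[carriers] = rng.choice(choices)
    keys = sorted(cols)
    alleles = np.stack([cols[bp] for bp in keys], axis=1) if keys else np.zeros((n, 0), np.uint8)
    out = HaplotypeMatrix(alleles, np.array(keys, dtype=float))
    return out.drop_nonsegregating()


def finite_site_project(m: HaplotypeMatrix, L_bp: int, seed: int) -> HaplotypeMatrix:
    """Project infinite-site mutations onto a discrete L_bp fragment.

    Each input column (one mutation event) receives a site index uniform
    on {1..L_bp}; mutations sharing a site apply successive state changes
    under a symmetric 4-allele model (each hit moves its carriers to a
    uniformly chosen different nucleotide).  Only segregating sites are
    kept; output positions are the 1-based bp indices.
    """
    if L_bp < 1:
        raise ValueError("L_bp must be >= 1")
    rng = generator(seed, "finite_site")
    sites = rng.integers(1, L_bp + 1, size=m.S)
    derived = [np.flatnonzero(m.alleles[:, j] == 1) for j in range(m.S)]
    return _project_mutations(m.n, derived, sites, rng)


def drop_mutations_conditional_finite(
    ts: tskit.TreeSequence,
    xi2p: int,
    xixp: int,
    L_bp: int,
    seed: int,
    max_rounds: int = 40,
) -> HaplotypeMatrix:
    """Finite-site analogue of conditional placement.

    Mutations of the requested folded classes are placed on the
    genealogies and projected onto L_bp discrete sites; because multiple
    hits merge or destroy sites, the realized post-projection spectrum is
    repaired iteratively (mutations added for deficits, removed for
    surpluses) until the segregating-site spectrum matches (xi2p, xixp)
    exactly, the scale on which an observed finite-site window is
    measured.  Projection-created folded singletons are retained (they are
    stripped by the statistics, as for observed data).
    """
    if L_bp < 1:
        raise ValueError("L_bp must be >= 1")
    n = ts.num_samples
    rng = generator(seed, "cond_finite")
    targets = [2] * int(xi2p) + [-1] * int(xixp)
    derived, _pos, _miss = _place_class_columns(ts, targets, rng)
    bps = list(rng.integers(1, L_bp + 1, size=len(derived)))

    best = None
    for _round in range(max_rounds):
        proj_rng = np.random.default_rng(rng.integers(2**31))
        out = _project_mutations(n, derived, bps, proj_rng)
        c = out.folded_counts()
        got2, gotx = int(np.sum(c == 2)), int(np.sum(c >= 3))
        best = out
        d2, dx = int(xi2p) - got2, int(xixp) - gotx
        if d2 == 0 and dx == 0:
            return out
        if d2 < 0 or dx < 0:
            # surplus: remove one random mutation and re-project
            j = int(rng.integers(len(derived)))
            derived.pop(j)
            bps.pop(j)
            continue
        extra = [2] * d2 + [-1] * dx
        new_derived, _p, _m = _place_class_columns(ts, extra, rng)
        derived.extend(new_derived)
        bps.extend(rng.integers(1, L_bp + 1, size=len(new_derived)))
    return best


def multiple_hit_probability(S: int, L_bp: int) -> float:
    """P(at least two of S uniformly placed mutations share a site).

    The exact birthday product 1 - prod_{i<S} (1 - i/L_bp); returns 1
    whenever S > L_bp.
    """
    if S < 0 or L_bp < 1:
        raise ValueError("require S >= 0 and L_bp >= 1")
    if S > L_bp:
        return 1.0
    i = np.arange(int(S), dtype=float)
    return float(1.0 - np.exp(np.log1p(-i / L_bp).sum()))


def mask_missing(m: HaplotypeMatrix, v_percent: float, seed: int) -> HaplotypeMatrix:
    """Mark round(v% of cells) as missing; drop columns no longer segregating.

    The masked coordinate pattern (in the pre-drop column indexing) is kept
    in ``meta['mask_pattern']`` with the retained columns in
    ``meta['kept_columns']`` so training sets can replicate it.
    """
    if not 0 <= v_percent <= 100:
        raise ValueError("v_percent must be in [0, 100]")
    rng = generator(seed, "mask")
    total = m.n * m.S
    k = int(round(v_percent / 100.0 * total))
    flat = rng.choice(total, size=k, replace=False)
    rows, cols = np.unravel_index(flat, (m.n, m.S))
    alleles = m.alleles.copy()
    alleles[rows, cols] = MISSING
    masked = HaplotypeMatrix(alleles, m.positions.copy(), window=m.window)
    keep = np.flatnonzero(masked.segregating_mask())
    out = masked.select_columns(keep)
    out.meta = {
        "mask_pattern": np.stack([rows, cols], axis=1),
        "kept_columns": keep,
    }
    return out
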
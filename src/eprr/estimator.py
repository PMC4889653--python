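"""Estimation of rho by boosted regression on summary statistics.

For a window with folded spectrum (xi2', xix'), a training set is
simulated conditional on that spectrum over a fixed grid of rho values
(100 replicates per grid point), a boosted additive model rho = f(SS) is
fitted, and the observed statistics are plugged in.  Two refinements from
the method: if the observed number of haplotypes exceeds the 95th
percentile of H at the top training rho (Hthres), the grid is extended
and the model refitted; and the raw prediction is de-biased by a linear
correction alpha = rho_hat / mean(rho_hat_s) over re-simulations at
rho_hat.

Models are cached per conditioning context so genome scans train each
unique (n, xi2', xix') combination once.  Training genealogies for the
grid are pooled per (n, rho, demography) and shared across contexts;
mutation placement is redrawn for every training replicate, and the
correction step always simulates fresh genealogies.
"""

from __future__ import annotations

import hashlib
import os
import pickle
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import tskit

from ._rng import derive_seed, generator
from .boosting import PSplineBooster
from .coalsim import (
    DemographyModel,
    PlacementError,
    SimContext,
    drop_mutations_conditional,
    drop_mutations_conditional_finite,
    simulate_trees,
)
from .haplotype import HaplotypeMatrix
from .sumstats import EmptyWindowError, SummaryStats, fold_spectrum, summarize

__all__ = [
    "DEFAULT_GRID",
    "EXTENDED_GRID",
    "default_grid",
    "extended_grid",
    "TrainingContext",
    "TrainingSet",
    "RegressionModel",
    "RhoEstimate",
    "EstimateOptions",
    "ModelCache",
    "WindowSkipped",
    "build_training_set",
    "fit_model",
    "predict",
    "maybe_extend",
    "linear_correction",
    "estimate_window",
    "combine_with_ldhat",
]

DEFAULT_GRID: tuple[float, ...] = (0, 0.5, 1, 2, 5, 10, 20, 40, 70, 110, 170)
EXTENDED_GRID: tuple[float, ...] = DEFAULT_GRID + (180, 190, 200, 220, 250, 300, 350)

#: guard for the alpha division in the linear correction
EPSILON = 1e-3


def default_grid() -> list[float]:
    """The training grid of rho values."""
    return list(DEFAULT_GRID)


def extended_grid() -> list[float]:
    """The training grid used when H_obs exceeds Hthres."""
    return list(EXTENDED_GRID)


class WindowSkipped(RuntimeError):
    """The window cannot be estimated (too few usable sites)."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass(frozen=True)
class TrainingContext:
    """Everything the training simulations are conditioned on.

    column_missing, when set, holds one tuple of masked row indices per
    conditioned column (xi2' columns first, then xix'), replicating the
    observed missing-data pattern in every training replicate.
    """

    n: int
    xi2p: int
    xixp: int
    column_missing: tuple[tuple[int, ...], ...] | None = None
    finite_site_length: int | None = None
    demography: DemographyModel | None = None

    def __post_init__(self) -> None:
        if self.n < 6:
            raise ValueError("training requires n >= 6")
        if self.xi2p < 0 or self.xixp < 0 or self.xi2p + self.xixp < 1:
            raise ValueError("xi2p + xixp must be >= 1")
        if self.column_missing is not None and self.finite_site_length is not None:
            raise ValueError(
                "missing-data and finite-site conditioning cannot be combined"
            )
        if self.column_missing is not None and len(self.column_missing) != (
            self.xi2p + self.xixp
        ):
            raise ValueError("column_missing must match the conditioned column count")

    def cache_key(self) -> str:
        h = hashlib.blake2b(digest_size=12)
        h.update(repr((self.n, self.xi2p, self.xixp, self.column_missing,
                       self.finite_site_length, self.demography)).encode())
        return h.hexdigest()

    def simulate_matrix(self, ts: tskit.TreeSequence, seed: int) -> HaplotypeMatrix:
        """One conditional replicate on the given genealogies."""
        if self.finite_site_length is not None:
            return drop_mutations_conditional_finite(
                ts, self.xi2p, self.xixp, self.finite_site_length, seed
            )
        cm = (
            [np.array(c, dtype=np.int64) for c in self.column_missing]
            if self.column_missing is not None
            else None
        )
        return drop_mutations_conditional(ts, self.xi2p, self.xixp, seed, cm)


@dataclass
class TrainingSet:
    rows: list[tuple[float, SummaryStats]]
    grid: tuple[float, ...]
    reps_per_rho: int


@dataclass
class RegressionModel:
    """A fitted boosted additive model with its training context."""

    fit: PSplineBooster
    context: TrainingContext
    grid: tuple[float, ...]
    h_thres: float
    extended: bool = False


@dataclass
class RhoEstimate:
    """A corrected window estimate with provenance."""

    rho_raw: float
    alpha: float  # NaN when the correction was skipped (epsilon rule)
    rho: float
    correction_reps: int
    extended: bool
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    xi2p: int = 0
    xixp: int = 0
    h_obs: int = 0


class _TreePool:
    """Shared training genealogies, keyed by (n, rho, demography)."""

    def __init__(self, seed: int):
        self.seed = seed
        self._pool: dict[tuple, list[tskit.TreeSequence]] = {}

    def get(self, n: int, rho: float, demography: DemographyModel | None, index: int):
        key = (n, float(rho), demography)
        seqs = self._pool.setdefault(key, [])
        while len(seqs) <= index:
            ctx = SimContext(
                n=n,
                rho=rho,
                demography=demography,
                seed=derive_seed(self.seed, "pool", n, float(rho), demography, len(seqs)),
            )
            seqs.append(simulate_trees(ctx))
        return seqs[index]


class ModelCache:
    """Fit-once storage of regression models plus the training tree pool.

    With ``cache_dir`` set, fitted models are persisted as versioned
    pickle files so later scans amortize training.
    """

    _VERSION = 1

    def __init__(
        self,
        seed: int = 1,
        training_reps: int = 100,
        cache_dir: str | None = None,
    ):
        self.seed = seed
        self.training_reps = training_reps
        self.cache_dir = cache_dir
        self.pool = _TreePool(derive_seed(seed, "treepool"))
        self._models: dict[tuple[str, tuple[float, ...]], RegressionModel] = {}
        self._tsets: dict[tuple[str, tuple[float, ...]], TrainingSet] = {}
        self.hits = 0
        self.builds = 0

    def _path(self, key: tuple[str, tuple[float, ...]]) -> str | None:
        if self.cache_dir is None:
            return None
        name = f"model_v{self._VERSION}_{key[0]}_{len(key[1])}.pkl"
        return os.path.join(self.cache_dir, name)

    def get_or_fit(
        self, ctx: TrainingContext, grid: Sequence[float] | None = None
    ) -> RegressionModel:
        grid = tuple(grid if grid is not None else DEFAULT_GRID)
        key = (ctx.cache_key(), grid)
        model = self._models.get(key)
        if model is not None:
            self.hits += 1
            return model
        path = self._path(key)
        if path is not None and os.path.exists(path):
            with open(path, "rb") as fh:
                model = pickle.load(fh)
            self._models[key] = model
            self.hits += 1
            return model
        train_seed = derive_seed(self.seed, "train", key[0])
        base_key = (key[0], tuple(DEFAULT_GRID))
        base = self._tsets.get(base_key)
        if base is not None and set(DEFAULT_GRID) < set(grid):
            # reuse the base-grid rows; per-rho seeds are grid-independent,
            # so this equals a from-scratch build on the extended grid
            missing = tuple(r for r in grid if r not in base.grid)
            extra = build_training_set(
                ctx, missing, reps=self.training_reps, seed=train_seed, pool=self.pool
            )
            ts_set = TrainingSet(
                rows=base.rows + extra.rows, grid=grid, reps_per_rho=self.training_reps
            )
        else:
            ts_set = build_training_set(
                ctx, grid, reps=self.training_reps, seed=train_seed, pool=self.pool
            )
        self._tsets[key] = ts_set
        model = fit_model(ts_set, ctx)
        model.extended = grid != DEFAULT_GRID
        self.builds += 1
        self._models[key] = model
        if path is not None:
            os.makedirs(self.cache_dir, exist_ok=True)
            with open(path, "wb") as fh:
                pickle.dump(model, fh)
        return model


@dataclass
class EstimateOptions:
    """Options for the window estimation pipeline."""

    training_reps: int = 100
    correction_reps: int = 100
    seed: int = 1
    cache: ModelCache | None = None
    min_sites: int = 2
    finite_site_length: int | None = None
    replicate_missing: bool = True


def build_training_set(
    ctx: TrainingContext,
    grid: Sequence[float] | None = None,
    reps: int = 100,
    seed: int = 1,
    pool: _TreePool | None = None,
) -> TrainingSet:
    """Simulate the conditional training set over the rho grid.

    Rows come in grid-major, replicate-minor order; every row carries the
    conditioning spectrum exactly.  Replicates whose placement degenerates
    (no admissible branch, or no usable site after masking) are redrawn on
    fresh genealogies.
    """
    grid = tuple(grid if grid is not None else DEFAULT_GRID)
    if pool is None:
        pool = _TreePool(derive_seed(seed, "localpool"))
    rows: list[tuple[float, SummaryStats]] = []
    for rho in grid:
        for k in range(reps):
            ss = None
            for attempt in range(20):
                try:
                    if attempt == 0:
                        ts = pool.get(ctx.n, rho, ctx.demography, k)
                    else:
                        ts = simulate_trees(
                            SimContext(
                                n=ctx.n,
                                rho=rho,
                                demography=ctx.demography,
                                seed=derive_seed(seed, "retry", rho, k, attempt),
                            )
                        )
                    m = ctx.simulate_matrix(ts, derive_seed(seed, "drop", rho, k, attempt))
                    ss = summarize(m)
                    break
                except (PlacementError, EmptyWindowError):
                    continue
            if ss is None:
                raise PlacementError(
                    f"could not realize a training replicate at rho={rho} "
                    f"for spectrum ({ctx.xi2p}, {ctx.xixp})"
                )
            rows.append((float(rho), ss))
    return TrainingSet(rows=rows, grid=grid, reps_per_rho=reps)


def _training_arrays(ts_set: TrainingSet) -> tuple[np.ndarray, np.ndarray]:
    X = np.array([ss.as_vector() for _, ss in ts_set.rows])
    y = np.array([rho for rho, _ in ts_set.rows])
    return X, y


def fit_model(ts_set: TrainingSet, ctx: TrainingContext) -> RegressionModel:
    """Fit the boosted additive model and compute Hthres.

    Hthres is the empirical 95th percentile of H among the training
    replicates at the maximum grid rho.
    """
    X, y = _training_arrays(ts_set)
    if len(np.unique(y)) < 2:
        raise ValueError("training set needs >= 2 distinct rho values")
    finite = np.isfinite(X).all(axis=1)
    if finite.sum() < len(X):
        X, y = X[finite], y[finite]
    if len(X) == 0 or np.allclose(X.std(axis=0), 0):
        raise ValueError("degenerate training set: summary statistics are constant")
    booster = PSplineBooster().fit(X, y)
    top = max(ts_set.grid)
    h_top = np.array([ss.H for rho, ss in ts_set.rows if rho == top])
    h_thres = float(np.percentile(h_top, 95))
    return RegressionModel(
        fit=booster, context=ctx, grid=ts_set.grid, h_thres=h_thres
    )


def predict(model: RegressionModel, ss: SummaryStats) -> float:
    """rho_hat = f(SS_obs), floored at zero."""
    val = float(model.fit.predict(ss.as_vector()[None, :])[0])
    return max(0.0, val)


def maybe_extend(
    model: RegressionModel,
    h_obs: int,
    cache: ModelCache,
) -> RegressionModel:
    """Refit on the extended grid when H_obs exceeds Hthres."""
    if h_obs <= model.h_thres:
        return model
    return cache.get_or_fit(model.context, EXTENDED_GRID)


def linear_correction(
    rho_hat: float,
    model: RegressionModel,
    ctx: TrainingContext,
    B: int = 100,
    seed: int = 1,
) -> RhoEstimate:
    """De-bias rho_hat: alpha = rho_hat / mean of re-estimates at rho_hat.

    B fresh datasets are simulated at rho = rho_hat under the same
    conditioning, each is re-estimated with the fitted model, and the
    estimate becomes alpha * rho_hat.  The 2.5/97.5 percentiles of the
    corrected re-estimates give a simple interval.  Below EPSILON the
    correction is skipped and flagged (alpha = NaN).
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    if rho_hat < 0:
        raise ValueError("rho_hat must be >= 0")
    base = RhoEstimate(
        rho_raw=rho_hat,
        alpha=float("nan"),
        rho=rho_hat,
        correction_reps=0,
        extended=model.extended,
        xi2p=ctx.xi2p,
        xixp=ctx.xixp,
    )
    if rho_hat < EPSILON:
        return base
    rho_s = []
    for b in range(B):
        for attempt in range(20):
            try:
                ts = simulate_trees(
                    SimContext(
                        n=ctx.n,
                        rho=rho_hat,
                        demography=ctx.demography,
                        seed=derive_seed(seed, "corr", b, attempt),
                    )
                )
                m = ctx.simulate_matrix(ts, derive_seed(seed, "corrdrop", b, attempt))
                rho_s.append(predict(model, summarize(m)))
                break
            except (PlacementError, EmptyWindowError):
                continue
    if len(rho_s) < 2:
        return base
    rho_s = np.array(rho_s)
    mean_s = float(rho_s.mean())
    if mean_s < EPSILON:
        return base
    alpha = rho_hat / mean_s
    corrected = alpha * rho_s
    return RhoEstimate(
        rho_raw=rho_hat,
        alpha=alpha,
        rho=alpha * rho_hat,
        correction_reps=len(rho_s),
        extended=model.extended,
        ci_low=float(np.percentile(corrected, 2.5)),
        ci_high=float(np.percentile(corrected, 97.5)),
        xi2p=ctx.xi2p,
        xixp=ctx.xixp,
    )


def _observed_context(m: HaplotypeMatrix, opts: EstimateOptions) -> TrainingContext:
    from .sumstats import strip_folded_singletons

    spec = fold_spectrum(m)
    column_missing = None
    if opts.replicate_missing and opts.finite_site_length is None:
        stripped = strip_folded_singletons(m)
        if np.any(stripped.missing_mask):
            column_missing = tuple(
                tuple(int(r) for r in np.flatnonzero(stripped.missing_mask[:, j]))
                for j in range(stripped.S)
            )
    return TrainingContext(
        n=m.n,
        xi2p=spec.xi2p,
        xixp=spec.xixp,
        column_missing=column_missing,
        finite_site_length=opts.finite_site_length,
    )


def estimate_window(m: HaplotypeMatrix, opts: EstimateOptions | None = None) -> RhoEstimate:
    """Full pipeline for one window.

    fold spectrum -> strip singletons -> summarize -> (cached) model fit
    -> predict -> grid extension check -> linear correction.
    Deterministic given opts.seed (and the cache's seed for training).
    """
    opts = opts or EstimateOptions()
    spec = fold_spectrum(m)
    usable = spec.xi2p + spec.xixp
    if usable < max(2, opts.min_sites):
        raise WindowSkipped(f"few_sites:{usable}")
    try:
        ss = summarize(m)
    except EmptyWindowError as e:
        raise WindowSkipped("empty") from e
    if not np.isfinite(ss.mean_r2):
        raise WindowSkipped("undefined_r2")
    cache = opts.cache or ModelCache(
        seed=derive_seed(opts.seed, "ephemeral-cache"),
        training_reps=opts.training_reps,
    )
    ctx = _observed_context(m, opts)
    model = cache.get_or_fit(ctx)
    rho_raw = predict(model, ss)
    model = maybe_extend(model, ss.H, cache)
    if model.extended:
        rho_raw = predict(model, ss)
    est = linear_correction(
        rho_raw,
        model,
        ctx,
        B=opts.correction_reps,
        seed=derive_seed(opts.seed, "correction"),
    )
    est.h_obs = ss.H
    return est


def combine_with_ldhat(rho_f: float, rho_l: float) -> float:
    """rho_comb: the average of this estimator's rho and an externally
    supplied composite-likelihood (LDhat) estimate."""
    if rho_f < 0 or rho_l < 0:
        raise ValueError("rates must be >= 0")
    return 0.5 * (rho_f + rho_l)
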
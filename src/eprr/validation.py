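"""Replicate experiments on simulated data.

These helpers reproduce the method's validation designs: datasets are
simulated under a known rho (with the mutation scheme fixed either by
theta or by the number of segregating sites S, optionally with missing
data, finite sites or non-equilibrium demography), each dataset is pushed
through the full estimation pipeline, and the corrected estimates are
collected.  Sharing one ModelCache across replicates mirrors genome-scan
practice: each unique folded-spectrum combination trains one model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import derive_seed
from .coalsim import (
    DemographyModel,
    SimContext,
    drop_mutations_fixed_S,
    drop_mutations_theta,
    finite_site_project,
    mask_missing,
    simulate_trees,
)
from .estimator import (
    EstimateOptions,
    ModelCache,
    RhoEstimate,
    WindowSkipped,
    estimate_window,
)
from .haplotype import HaplotypeMatrix

__all__ = ["Condition", "simulate_dataset", "run_replicates", "mean_estimate"]


@dataclass(frozen=True)
class Condition:
    """One validation design point.

    Exactly one of ``theta`` (mutation rate fixed) or ``S`` (segregating
    sites fixed) must be set.  ``missing_percent`` masks that percentage
    of cells; ``finite_site_length`` projects the mutations onto a
    discrete fragment of that many bp; ``demography`` simulates the data
    under a non-equilibrium history (the estimator still trains under the
    standard neutral model, as for real data of unknown history).
    """

    n: int
    rho: float
    theta: float | None = None
    S: int | None = None
    missing_percent: float = 0.0
    finite_site_length: int | None = None
    demography: DemographyModel | None = None

    def __post_init__(self) -> None:
        if (self.theta is None) == (self.S is None):
            raise ValueError("set exactly one of theta or S")


def simulate_dataset(cond: Condition, seed: int) -> HaplotypeMatrix:
    """One dataset under the condition; deterministic given seed."""
    ts = simulate_trees(
        SimContext(
            n=cond.n,
            rho=cond.rho,
            demography=cond.demography,
            seed=derive_seed(seed, "data-trees"),
        )
    )
    if cond.theta is not None:
        m = drop_mutations_theta(ts, cond.theta, derive_seed(seed, "data-mut"))
    else:
        m = drop_mutations_fixed_S(ts, cond.S, derive_seed(seed, "data-mut"))
    if cond.finite_site_length is not None:
        m = finite_site_project(m, cond.finite_site_length, derive_seed(seed, "data-fs"))
    if cond.missing_percent > 0:
        m = mask_missing(m, cond.missing_percent, derive_seed(seed, "data-mask"))
    return m


def run_replicates(
    cond: Condition,
    reps: int,
    seed: int,
    cache: ModelCache,
    correction_reps: int = 100,
) -> list[RhoEstimate]:
    """Estimate ``reps`` independent datasets; skipped windows are dropped."""
    out: list[RhoEstimate] = []
    for k in range(reps):
        m = simulate_dataset(cond, derive_seed(seed, "rep", k))
        opts = EstimateOptions(
            training_reps=cache.training_reps,
            correction_reps=correction_reps,
            seed=derive_seed(seed, "est", k),
            cache=cache,
            finite_site_length=cond.finite_site_length,
        )
        try:
            out.append(estimate_window(m, opts))
        except WindowSkipped:
            continue
    return out


def mean_estimate(estimates: list[RhoEstimate]) -> float:
    return float(np.mean([e.rho for e in estimates]))
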
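"""Component-wise gradient boosting with smooth univariate base learners.

The regression rho = f(SS) is a boosted additive model: at each iteration
the penalized cubic B-spline (P-spline) smoother of one predictor — the
one that best fits the current residual — is added with a small learning
rate.  Squared-error loss throughout; the base-learner flexibility is
controlled by fixing the effective degrees of freedom of each smoother.

Predictors are clamped to their training range before evaluation, so the
fitted additive functions extrapolate as constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["PSplineBooster"]


def _design(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    B = BSpline.design_matrix(x, knots, 3)
    return np.asarray(B.todense())


def _spline_knots(lo: float, hi: float, n_segments: int) -> np.ndarray:
    step = (hi - lo) / n_segments
    inner = np.linspace(lo, hi, n_segments + 1)  # endpoints exact
    return np.concatenate(
        [lo - step * np.array([3.0, 2.0, 1.0]), inner, hi + step * np.array([1.0, 2.0, 3.0])]
    )


def _lambda_for_df(B: np.ndarray, P: np.ndarray, df: float) -> float:
    """Bisection on log-lambda so that trace of the smoother equals df."""
    BtB = B.T @ B

    def trace(lam: float) -> float:
        H = np.linalg.solve(BtB + lam * P + 1e-10 * np.eye(len(P)), BtB)
        return float(np.trace(H))

    lo, hi = -12.0, 16.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if trace(10**mid) > df:
            lo = mid
        else:
            hi = mid
    return 10 ** (0.5 * (lo + hi))


@dataclass
class _BaseLearner:
    knots: np.ndarray
    lo: float
    hi: float
    coef: np.ndarray
    solver: np.ndarray = field(repr=False)  # maps residual -> spline coefficients
    design: np.ndarray = field(repr=False)

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        xc = np.clip(x, self.lo, self.hi)
        return _design(xc, self.knots) @ self.coef


class PSplineBooster:
    """Boosted additive regression of a response on a few predictors.

    Parameters mirror the usual componentwise-boosting defaults: cubic
    P-splines with ``n_segments`` equal-width segments and ``df`` effective
    degrees of freedom per learner, learning rate ``nu``, ``mstop``
    iterations, no early stopping.  Deterministic; row order of the
    training set does not affect the fit.
    """

    def __init__(
        self,
        n_segments: int = 20,
        df: float = 4.0,
        nu: float = 0.1,
        mstop: int = 250,
    ):
        self.n_segments = n_segments
        self.df = df
        self.nu = nu
        self.mstop = mstop
        self.offset_: float | None = None
        self.learners_: list[_BaseLearner | None] = []

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PSplineBooster":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be (m, p) with one response per row")
        m, p = X.shape
        self.offset_ = float(y.mean())
        self.learners_ = []
        for j in range(p):
            lo, hi = float(X[:, j].min()), float(X[:, j].max())
            if hi - lo < 1e-12:
                self.learners_.append(None)  # uninformative constant predictor
                continue
            knots = _spline_knots(lo, hi, self.n_segments)
            B = _design(np.clip(X[:, j], lo, hi), knots)
            D = np.diff(np.eye(B.shape[1]), n=2, axis=0)
            P = D.T @ D
            lam = _lambda_for_df(B, P, self.df)
            solver = np.linalg.solve(
                B.T @ B + lam * P + 1e-10 * np.eye(B.shape[1]), B.T
            )
            self.learners_.append(
                _BaseLearner(knots, lo, hi, np.zeros(B.shape[1]), solver, B)
            )
        if all(l is None for l in self.learners_):
            raise ValueError("all predictors are constant; cannot fit")

        r = y - self.offset_
        active = [j for j, l in enumerate(self.learners_) if l is not None]
        for _ in range(self.mstop):
            best_j, best_ssr, best_coef, best_fit = -1, np.inf, None, None
            for j in active:
                learner = self.learners_[j]
                c = learner.solver @ r
                fit = learner.design @ c
                ssr = float(np.sum((r - fit) ** 2))
                if ssr < best_ssr - 1e-12:
                    best_j, best_ssr, best_coef, best_fit = j, ssr, c, fit
            self.learners_[best_j].coef += self.nu * best_coef
            r = r - self.nu * best_fit
        self.residual_ = r
        for learner in self.learners_:  # drop fit-time workspaces; keep models small
            if learner is not None:
                learner.solver = None
                learner.design = None
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.full(len(X), self.offset_)
        for j, learner in enumerate(self.learners_):
            if learner is not None:
                out = out + learner.evaluate(X[:, j])
        return out
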
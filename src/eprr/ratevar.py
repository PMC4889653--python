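"""Variable recombination rates within windows.

Overlapping sliding windows (step = half the window) share half-window
rates: for three consecutive window estimates, rho_1 = x1 + x2,
rho_2 = x2 + x3, rho_3 = x3 + x4 for the four underlying half-windows.
Each triple is solved by (1) nonnegativity, (2) least squares on the
window sums, (3) maximizing the product x1*x2*x3*x4 among the tied least
squares solutions; sliding the triple along the track re-estimates each
half-window, and the final rate is the mean of all its candidates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

__all__ = ["DecomposedTrack", "solve_triple", "decompose"]

_A = np.array(
    [
        [1.0, 1.0, 0.0, 0.0],
        [0.0, 1.0, 1.0, 0.0],
        [0.0, 0.0, 1.0, 1.0],
    ]
)
# null-space direction of _A: moving along it leaves all window sums fixed
_D = np.array([1.0, -1.0, 1.0, -1.0])


def solve_triple(r1: float, r2: float, r3: float) -> tuple[float, float, float, float]:
    """Half-window rates for three overlapping window estimates.

    Returns the nonnegative minimizer of
    f1 = (x1+x2-r1)^2 + (x2+x3-r2)^2 + (x3+x4-r3)^2; the minimizer set is
    a segment along (1,-1,1,-1), on which the product x1*x2*x3*x4 (a
    quartic in the segment parameter) is maximized in closed form.  When
    the product vanishes on the whole segment the midpoint is returned.
    """
    r = np.array([r1, r2, r3], dtype=float)
    if np.any(r < 0):
        raise ValueError("window estimates must be >= 0")
    x, _ = nnls(_A, r)
    # feasible parameter range along the null-space direction
    t_lo = max(-x[0], -x[2])
    t_hi = min(x[1], x[3])
    if t_hi < t_lo:  # numerically degenerate; keep the NNLS point
        return tuple(np.maximum(x, 0.0))

    def product(t: np.ndarray) -> np.ndarray:
        return (x[0] + t) * (x[1] - t) * (x[2] + t) * (x[3] - t)

    candidates = [t_lo, t_hi]
    # stationary points of the quartic product
    coeff = np.polynomial.polynomial.polyfromroots([-x[0], x[1], -x[2], x[3]])
    # product(t) = (x1+t)(x2-t)(x3+t)(x4-t) = poly(t) with sign (+1)(-1)(+1)(-1)
    poly = np.polynomial.Polynomial(coeff)
    deriv = poly.deriv()
    for root in deriv.roots():
        if abs(root.imag) < 1e-9 and t_lo < root.real < t_hi:
            candidates.append(float(root.real))
    cand = np.array(candidates)
    vals = product(cand)
    best = float(vals.max())
    if best <= 1e-12:  # product zero over the whole segment: take midpoint
        t = 0.5 * (t_lo + t_hi)
    else:
        t = float(cand[int(np.argmax(vals))])
    out = x + t * _D
    return tuple(float(max(v, 0.0)) for v in out)


@dataclass
class DecomposedTrack:
    """Half-window rates averaged over all contributing triple systems."""

    intervals: list[tuple[int, int]]
    rates: np.ndarray
    support: np.ndarray

    def __len__(self) -> int:
        return len(self.intervals)


def _check_run(starts: np.ndarray, step: int) -> None:
    if np.any(np.diff(starts) != step):
        raise ValueError("windows must tile regularly at the given step")


def decompose(
    window_estimates: list[tuple[tuple[int, int], float]],
    window_len: int,
    step: int | None = None,
) -> DecomposedTrack:
    """Decompose a track of overlapping window estimates into half-window
    rates.

    ``window_estimates`` is an ordered list of ((start, end), rho_hat) with
    end - start == window_len and starts advancing by ``step`` =
    window_len / 2.  Runs separated by gaps (skipped windows) are
    decomposed independently; runs shorter than three windows are ignored
    (no constraint system exists for them).
    """
    step = step if step is not None else window_len // 2
    if step * 2 != window_len:
        raise ValueError("decomposition requires step = window_len / 2")
    if len(window_estimates) < 3:
        raise ValueError("need at least 3 window estimates")
    starts = np.array([iv[0] for iv, _ in window_estimates])
    ends = np.array([iv[1] for iv, _ in window_estimates])
    rhos = np.array([r for _, r in window_estimates], dtype=float)
    if np.any(ends - starts != window_len):
        raise ValueError("all windows must have length window_len")
    if np.any(np.diff(starts) <= 0):
        raise ValueError("windows must be ordered and distinct")
    if np.any(np.diff(starts) % step != 0):
        raise ValueError("window starts must be multiples of the step apart")

    # split into contiguous runs (consecutive windows step apart)
    breaks = np.flatnonzero(np.diff(starts) != step)
    run_bounds = np.concatenate([[0], breaks + 1, [len(starts)]])

    intervals: list[tuple[int, int]] = []
    rates: list[float] = []
    support: list[int] = []
    for a, b in zip(run_bounds[:-1], run_bounds[1:]):
        W = b - a
        if W < 3:
            continue
        _check_run(starts[a:b], step)
        n_half = W + 1
        acc = np.zeros(n_half)
        cnt = np.zeros(n_half, dtype=int)
        for k in range(W - 2):
            x = solve_triple(rhos[a + k], rhos[a + k + 1], rhos[a + k + 2])
            for i, v in enumerate(x):
                acc[k + i] += v
                cnt[k + i] += 1
        s0 = starts[a]
        for h in range(n_half):
            intervals.append((int(s0 + h * step), int(s0 + (h + 1) * step)))
        rates.extend(acc / np.maximum(cnt, 1))
        support.extend(cnt)
    return DecomposedTrack(
        intervals=intervals, rates=np.array(rates), support=np.array(support)
    )
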
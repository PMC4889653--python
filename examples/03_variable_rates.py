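"""Decompose overlapping window estimates into half-window rates.

When rho varies within windows, scanning with step = window/2 and solving
the overlapping constraint systems recovers rates at twice the
resolution.  Here a hotspot doubles the rate of one half-window; the
decomposition localizes it.
"""

import numpy as np

from eprr import decompose, solve_triple

# one constraint system: rho1 = x1+x2, rho2 = x2+x3, rho3 = x3+x4
print("solve_triple(2, 2, 2) ->", solve_triple(2, 2, 2))
print("solve_triple(2, 0, 2) ->", solve_triple(2, 0, 2))
print()

# a track of 50 kb windows, step 25 kb; true half-window rates are 1
# except a hotspot (rate 4) in the fifth half-window
true_half = np.array([1, 1, 1, 1, 4, 1, 1, 1])
window_sums = true_half[:-1] + true_half[1:]
windows = [
    ((k * 25_000, k * 25_000 + 50_000), float(window_sums[k]))
    for k in range(len(window_sums))
]
track = decompose(windows, window_len=50_000)
print("half-window  interval          rate   (true)  support")
for (s, e), r, c, t in zip(track.intervals, track.rates, track.support, true_half):
    print(f"             [{s:>7}, {e:>7})  {r:5.2f}  ({t})     {c}")
print()
print("Each half-window rate is the mean over all 3-window systems covering")
print("it; the hotspot stands out at 25 kb resolution.")
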
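"""Independent brute-force oracles shared across test modules."""

import numpy as np


def dense_duration(times, U, factor=1000):
    """Super-threshold interval measure on a dense grid (brute force).

    Threshold = median of the samples; the piecewise-linear interpolant is
    evaluated on a grid `factor` times finer than the sampling and the
    longest run of strictly-above samples is counted.
    """
    thr = np.median(U)
    tt = np.linspace(times[0], times[-1], factor * (len(times) - 1) + 1)
    uu = np.interp(tt, times, U)
    above = uu > thr
    best = run = 0
    for a in above:
        run = run + 1 if a else 0
        best = max(best, run)
    return best * (tt[1] - tt[0])
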
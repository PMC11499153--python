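"""Shared test fixtures-in-code: small synthetic frames and brute-force
oracles that stay independent of the implementation they check."""

import numpy as np


def gaussian_blob(shape=(96, 96), center=(48, 48), sigma=8.0, amp=100.0):
    rr, cc = np.indices(shape)
    return amp * np.exp(-(((rr - center[0]) ** 2 + (cc - center[1]) ** 2)
                          / (2 * sigma**2)))


def brute_force_intermeans(frame):
    """Exhaustive intermeans fixed-point search, exact for integer frames.

    Every integer split boundary t (class low = pixels <= t, high = > t)
    is tried; the fixed point is the split whose intermean
    m = (mean_low + mean_high)/2 falls back into [t, t+1], i.e. is
    self-consistent.  Falls back to the split minimising |m − (t+0.5)| if
    no exactly consistent split exists.
    """
    vals = np.asarray(frame).ravel().astype(int)
    best, best_gap = None, np.inf
    for t in range(vals.min(), vals.max()):
        low, high = vals[vals <= t], vals[vals > t]
        if low.size == 0 or high.size == 0:
            continue
        m = 0.5 * (low.mean() + high.mean())
        if t <= m <= t + 1:
            return m
        gap = abs(m - (t + 0.5))
        if gap < best_gap:
            best, best_gap = m, gap
    return best
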
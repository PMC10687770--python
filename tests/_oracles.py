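"""Independent brute-force oracles shared across test modules."""

import numpy as np


def brute_force_window_maxima(a, b, window_frames, step_frames, max_lag):
    """Independent oracle: exhaustive loop over windows and lags.

    Pearson correlation of a[s : s+W-l] with b[s+l : s+W]; zero-variance
    segments count as correlation 0 at that lag.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    maxima = []
    start = 0
    while start + window_frames <= a.shape[0]:
        best = -np.inf
        for lag in range(max_lag + 1):
            x = a[start : start + window_frames - lag]
            y = b[start + lag : start + window_frames]
            xd = x - x.mean()
            yd = y - y.mean()
            denom = np.sqrt((xd @ xd) * (yd @ yd))
            r = 0.0 if denom == 0.0 else float(xd @ yd / denom)
            best = max(best, r)
        maxima.append(best)
        start += step_frames
    return np.asarray(maxima)
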
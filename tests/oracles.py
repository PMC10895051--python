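"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive: per-index/per-pixel Python loops that transcribe each
rule literally. They share no code with the package internals.
"""

from __future__ import annotations

import numpy as np


def brute_force_inflections(values, margin):
    """Literal per-index application of the trajectory rule."""
    v = list(values)
    n = len(v)
    highs, lows, rejected = [], [], []
    for i in range(margin, n - margin):
        is_high = all(v[i - k - 1] < v[i - k] for k in range(margin)) and all(
            v[i + k] > v[i + k + 1] for k in range(margin)
        )
        is_low = all(v[i - k - 1] > v[i - k] for k in range(margin)) and all(
            v[i + k] < v[i + k + 1] for k in range(margin)
        )
        candidate = (v[i - 1] < v[i] > v[i + 1]) or (v[i - 1] > v[i] < v[i + 1])
        if is_high:
            highs.append(i)
        elif is_low:
            lows.append(i)
        elif candidate:
            rejected.append(i)
    return highs, lows, rejected


def brute_force_contrast(frame, window_size):
    """Per-pixel windowed K = population SD / mean; NaN where invalid."""
    half = window_size // 2
    rows, cols = frame.shape
    k = np.full((rows, cols), np.nan)
    valid = np.zeros((rows, cols), dtype=bool)
    for r in range(half, rows - half):
        for c in range(half, cols - half):
            win = frame[r - half : r + half + 1, c - half : c + half + 1]
            mu = win.mean()
            if mu <= 0:
                continue
            k[r, c] = win.std(ddof=0) / mu
            valid[r, c] = True
    return k, valid


def brute_force_roi_mean(values, valid, roi):
    """Direct summation over valid ROI pixels."""
    total, count = 0.0, 0
    rows, cols = values.shape
    for r in range(rows):
        for c in range(cols):
            if roi[r, c] and valid[r, c]:
                total += values[r, c]
                count += 1
    return total / count


def brute_force_trapezoid(t, y):
    """Pairwise trapezoid summation."""
    area = 0.0
    for i in range(len(t) - 1):
        area += (t[i + 1] - t[i]) * (y[i] + y[i + 1]) / 2.0
    return area
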
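"""Independent reference implementations used only by the tests.

The Hough oracle is a literal triple loop over every (yc, xc, r)
accumulator cell, re-counting outline pixels on the midpoint circle —
the same rasterization as the production accumulator but a completely
separate accumulation path (per-cell counting instead of per-pixel
vote scattering). Compiled with numba so exhaustive comparison stays
fast; the arithmetic is plain integer counting either way.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from cryoev._raster import circle_offsets


@njit(cache=False)
def _count_votes(outline, dy, dx, r_start, r_count, acc):
    h, w = outline.shape
    n_r = r_start.shape[0]
    for yc in range(h):
        for xc in range(w):
            for ri in range(n_r):
                votes = 0
                for k in range(r_start[ri], r_start[ri] + r_count[ri]):
                    y = yc + dy[k]
                    x = xc + dx[k]
                    if 0 <= y < h and 0 <= x < w and outline[y, x]:
                        votes += 1
                acc[yc, xc, ri] = votes


def brute_force_hough(outline: np.ndarray, r_min: int, r_max: int) -> np.ndarray:
    """Exhaustive vote counts acc[y, x, r - r_min] for every cell."""
    outline = np.ascontiguousarray(np.asarray(outline).astype(np.bool_))
    radii = range(r_min, r_max + 1)
    dy_all, dx_all, starts, counts = [], [], [], []
    pos = 0
    for r in radii:
        dy, dx = circle_offsets(r)
        dy_all.append(np.asarray(dy))
        dx_all.append(np.asarray(dx))
        starts.append(pos)
        counts.append(len(dy))
        pos += len(dy)
    dy_flat = np.concatenate(dy_all).astype(np.int64)
    dx_flat = np.concatenate(dx_all).astype(np.int64)
    acc = np.zeros((outline.shape[0], outline.shape[1], len(starts)), dtype=np.int64)
    _count_votes(outline, dy_flat, dx_flat,
                 np.asarray(starts, dtype=np.int64),
                 np.asarray(counts, dtype=np.int64), acc)
    return acc


def median_filter_3x3(arr: np.ndarray) -> np.ndarray:
    """Direct 3x3 median by sorting each neighbourhood (zero padded)."""
    a = np.asarray(arr, dtype=float)
    padded = np.pad(a, 1, mode="constant")
    stack = np.stack([padded[i:i + a.shape[0], j:j + a.shape[1]]
                      for i in range(3) for j in range(3)])
    return np.median(stack, axis=0)


def fft_amplitude_at(img: np.ndarray, period_px: float, axis: int = 1) -> float:
    """Amplitude of the sinusoidal component with the given period along
    ``axis`` (used to measure bandpass attenuation)."""
    n = img.shape[axis]
    k = int(round(n / period_px))
    spec = np.fft.rfft(img.mean(axis=1 - axis))
    return 2.0 * np.abs(spec[k]) / n
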
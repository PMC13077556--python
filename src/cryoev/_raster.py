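"""Midpoint-circle rasterization shared by the simulator, the Hough
voting templates and the test oracles.

A single rasterization is used everywhere so that the normalized vote
score of a complete ideal ring is exactly 1.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from skimage.draw import circle_perimeter

__all__ = ["circle_offsets", "perimeter_count", "arc_offsets", "draw_ring", "draw_arc"]


@lru_cache(maxsize=512)
def circle_offsets(radius: int) -> tuple:
    """Unique (dy, dx) integer offsets of the midpoint circle of ``radius``.

    Returned as two read-only int arrays (dy, dx), sorted in raster order.
    """
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    rr, cc = circle_perimeter(0, 0, int(radius), method="bresenham")
    pts = np.unique(np.stack([rr, cc], axis=1), axis=0)
    dy = pts[:, 0].copy()
    dx = pts[:, 1].copy()
    dy.setflags(write=False)
    dx.setflags(write=False)
    return dy, dx


def perimeter_count(radius: int) -> int:
    """Number of pixels on the ideal rasterized circle of ``radius``."""
    return len(circle_offsets(radius)[0])


def arc_offsets(radius: int, fraction: float, theta0: float = 0.0) -> tuple:
    """Offsets of a partial arc covering ``fraction`` of the circle.

    The arc spans angles ``[theta0, theta0 + fraction*2*pi)`` measured
    from the +x axis with y increasing downward (raster convention).
    """
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0,1], got {fraction}")
    dy, dx = circle_offsets(radius)
    if fraction == 1.0:
        return dy, dx
    ang = np.mod(np.arctan2(dy, dx) - theta0, 2 * np.pi)
    keep = ang < fraction * 2 * np.pi
    return dy[keep], dx[keep]


def _paint(shape, cy, cx, dy, dx, out=None):
    if out is None:
        out = np.zeros(shape, dtype=bool)
    yy = cy + dy
    xx = cx + dx
    ok = (yy >= 0) & (yy < shape[0]) & (xx >= 0) & (xx < shape[1])
    out[yy[ok], xx[ok]] = True
    return out


def draw_ring(shape, cy: int, cx: int, radius: int, out=None) -> np.ndarray:
    """Rasterize a 1-px circle perimeter into a boolean image."""
    dy, dx = circle_offsets(radius)
    return _paint(shape, cy, cx, dy, dx, out)


def draw_arc(shape, cy: int, cx: int, radius: int, fraction: float,
             theta0: float = 0.0, out=None) -> np.ndarray:
    """Rasterize a partial circle perimeter into a boolean image."""
    dy, dx = arc_offsets(radius, fraction, theta0)
    return _paint(shape, cy, cx, dy, dx, out)
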
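"""From segmentation masks to particle records and size distributions.

The Hough circle transform accumulates votes over (y, x, r) from an
outline image (edge-detected disc boundaries or skeletonized bilayer
rings). The score of a candidate circle is its vote count divided by
the pixel count of the ideal midpoint-rasterized circle of that radius,
so a complete ideal ring scores exactly 1 and an arc covering a
fraction alpha of the circle scores ~alpha — which is what makes the
transform robust to partially segmented bilayers. Default thresholds:
0.8 for filled-circle outlines, 0.5 for rings.

Area-based sizing uses the area-equivalent diameter d = 2*sqrt(A/pi),
which also applies to oval particles.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from ._raster import circle_offsets, perimeter_count
from .types import HoughConfig, ParticleRecord, SegmentationMask, SizeDistribution

__all__ = [
    "mask_to_outlines",
    "hough_accumulate",
    "hough_circles",
    "area_to_diameter",
    "component_records",
    "exclude_artifacts",
    "size_distribution",
]


# ---------------------------------------------------------------------------
# outlines


def mask_to_outlines(mask, mode: str = "edge") -> np.ndarray:
    """Outline a binary mask for Hough voting.

    ``edge``: boundary pixels of filled components (mask minus its
    erosion) — used for filled particle segmentations. ``skeleton``:
    1-px medial lines — used for ring-shaped bilayer segmentations.
    Both preserve topology: a filled disc gives one closed boundary, an
    annulus skeleton one closed ring.
    """
    if isinstance(mask, SegmentationMask):
        binary = mask.binary
    else:
        binary = np.asarray(mask)
        if binary.dtype != bool:
            vals = np.unique(binary)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError("mask_to_outlines expects a binary mask")
            binary = binary.astype(bool)
    if mode == "edge":
        eroded = ndimage.binary_erosion(binary, structure=np.ones((3, 3)),
                                        border_value=0)
        return binary & ~eroded
    if mode == "skeleton":
        return morphology.skeletonize(binary)
    raise ValueError(f"mode must be 'edge' or 'skeleton', got {mode!r}")


# ---------------------------------------------------------------------------
# Hough circle transform


def hough_accumulate(outline: np.ndarray, r_min: int, r_max: int) -> np.ndarray:
    """Vote accumulator: acc[y, x, i] = number of outline pixels lying on
    the midpoint circle of radius ``r_min + i`` centred at (y, x).

    Exact integer counts (no FFT rounding): each outline pixel casts one
    vote per circle template pixel.
    """
    outline = np.asarray(outline).astype(bool)
    h, w = outline.shape
    radii = np.arange(r_min, r_max + 1)
    acc = np.zeros((h, w, len(radii)), dtype=np.int32)
    ys, xs = np.nonzero(outline)
    if len(ys) == 0:
        return acc
    for i, r in enumerate(radii):
        dy, dx = circle_offsets(int(r))
        plane = acc[:, :, i]
        # a pixel at p votes for centres at p - offset
        for oy, ox in zip(dy, dx):
            cy = ys - oy
            cx = xs - ox
            ok = (cy >= 0) & (cy < h) & (cx >= 0) & (cx < w)
            np.add.at(plane, (cy[ok], cx[ok]), 1)
    return acc


def _nms(candidates: list) -> list:
    """Greedy non-maximum suppression.

    Candidates are (score, r, y, x), processed in descending score
    (ties: smaller radius, then raster order). A candidate is suppressed
    when its centre lies within max(r_kept, r_new)/2 of an accepted peak
    AND the radii differ by < 25% — so concentric rings of multilamellar
    vesicles survive while near-duplicate peaks collapse.
    """
    order = sorted(candidates, key=lambda c: (-c[0], c[1], c[2], c[3]))
    kept = []
    for score, r, y, x in order:
        suppressed = False
        for ks, kr, ky, kx in kept:
            if (math.hypot(y - ky, x - kx) < max(kr, r) / 2.0
                    and abs(r - kr) < 0.25 * max(kr, r)):
                suppressed = True
                break
        if not suppressed:
            kept.append((score, r, y, x))
    return kept


def hough_circles(outline: np.ndarray, cfg: HoughConfig, pixel_size: float,
                  mode: str = "rings", class_name: str = "EV_bilayer") -> list:
    """Detect circles/partial rings in an outline image.

    ``mode='rings'`` applies the ring threshold (default 0.5, partial
    arcs allowed); ``mode='circles'`` the stricter circle threshold
    (default 0.8). Records carry radius in pixels and diameter
    = 2 * r * pixel_size in nm.
    """
    outline = np.asarray(outline).astype(bool)
    h, w = outline.shape
    if cfg.r_max >= min(h, w) / 2:
        raise ValueError(
            f"r_max={cfg.r_max} must be < half the smaller image dimension "
            f"({min(h, w)})")
    if mode == "rings":
        threshold = cfg.score_threshold_rings
        source = "hough_ring"
    elif mode == "circles":
        threshold = cfg.score_threshold_circles
        source = "hough_circle"
    else:
        raise ValueError(f"mode must be 'rings' or 'circles', got {mode!r}")

    acc = hough_accumulate(outline, cfg.r_min, cfg.r_max)
    perim = np.array([perimeter_count(r) for r in range(cfg.r_min, cfg.r_max + 1)],
                     dtype=np.float64)
    scores = acc / perim[None, None, :]
    ys, xs, ri = np.nonzero(scores >= threshold)
    candidates = [(float(scores[y, x, i]), int(cfg.r_min + i), int(y), int(x))
                  for y, x, i in zip(ys, xs, ri)]
    kept = _nms(candidates)

    records = []
    for score, r, y, x in kept:
        records.append(ParticleRecord(
            class_name=class_name, y=float(y), x=float(x), radius_px=float(r),
            diameter_nm=2.0 * r * pixel_size, score=score, source=source,
            border_truncated=(y - r < 0 or x - r < 0 or y + r >= h or x + r >= w),
        ))
    return records


# ---------------------------------------------------------------------------
# area-based sizing


def area_to_diameter(area: float) -> float:
    """Area-equivalent diameter d = 2*sqrt(A/pi) (nm from nm^2)."""
    if area <= 0:
        raise ValueError(f"area must be > 0, got {area}")
    return 2.0 * math.sqrt(area / math.pi)


def component_records(mask, pixel_size: float, min_area: int = 5,
                      class_name: str = None) -> list:
    """Connected components (8-connectivity) of a filled-particle mask as
    area-sourced records. Components smaller than ``min_area`` px are
    dropped; two touching particles merge into a single component (a
    documented limitation of area-based sizing).
    """
    if isinstance(mask, SegmentationMask):
        binary = mask.binary
        class_name = class_name or mask.class_name
    else:
        binary = np.asarray(mask).astype(bool)
        class_name = class_name or "particle"
    h, w = binary.shape
    labels = measure.label(binary, connectivity=2)
    records = []
    for prop in measure.regionprops(labels):
        if prop.area < min_area:
            continue
        area_nm2 = prop.area * pixel_size**2
        d_nm = area_to_diameter(area_nm2)
        y, x = prop.centroid
        y0, x0, y1, x1 = prop.bbox
        records.append(ParticleRecord(
            class_name=class_name, y=float(y), x=float(x),
            radius_px=d_nm / (2.0 * pixel_size), diameter_nm=d_nm,
            score=1.0, source="area",
            border_truncated=(y0 == 0 or x0 == 0 or y1 == h or x1 == w),
        ))
    return records


# ---------------------------------------------------------------------------
# artifact exclusion


def exclude_artifacts(records: list, image_shape: tuple,
                      hole_center: tuple = None, hole_radius_px: float = None,
                      ice_mask: np.ndarray = None,
                      rim_radius_tol: float = 0.15, rim_center_tol_px: float = 20.0,
                      rim_tangent_tol_px: float = 3.0,
                      ice_overlap_threshold: float = 0.3) -> list:
    """Flag (never delete) records caused by known artifacts.

    Rules, each with a logged reason:
      hole_rim        detected circle consistent with the carbon-hole rim:
                      either concentric with it (radius within
                      ``rim_radius_tol`` relative tolerance of the rim
                      radius, centre within ``rim_center_tol_px``), or
                      osculating the rim line — a small circle fitted to a
                      stretch of rim arc has its centre at distance
                      R_rim -/+ r from the hole centre (within
                      ``rim_tangent_tol_px``)
      border_truncated circle extends beyond the image bounds
      ice_overlap     more than ``ice_overlap_threshold`` of the circle
                      area overlaps the ice-class mask
    """
    h, w = image_shape
    out = []
    for rec in records:
        reason = ""
        if hole_center is not None and hole_radius_px is not None:
            d_center = math.hypot(rec.y - hole_center[0], rec.x - hole_center[1])
            if (abs(rec.radius_px - hole_radius_px) <= rim_radius_tol * hole_radius_px
                    and d_center <= rim_center_tol_px):
                reason = "hole_rim"
            elif (abs(d_center - (hole_radius_px - rec.radius_px)) <= rim_tangent_tol_px
                  or abs(d_center - (hole_radius_px + rec.radius_px)) <= rim_tangent_tol_px):
                reason = "hole_rim"
        if not reason and rec.border_truncated:
            reason = "border_truncated"
        if not reason and ice_mask is not None:
            r = max(int(round(rec.radius_px)), 1)
            y0, y1 = max(int(rec.y) - r, 0), min(int(rec.y) + r + 1, h)
            x0, x1 = max(int(rec.x) - r, 0), min(int(rec.x) + r + 1, w)
            yy, xx = np.mgrid[y0:y1, x0:x1]
            inside = (yy - rec.y) ** 2 + (xx - rec.x) ** 2 <= r**2
            n_inside = int(inside.sum())
            if n_inside > 0:
                frac = float((ice_mask[y0:y1, x0:x1] & inside).sum()) / n_inside
                if frac > ice_overlap_threshold:
                    reason = "ice_overlap"
        if reason:
            out.append(ParticleRecord(
                class_name=rec.class_name, y=rec.y, x=rec.x,
                radius_px=rec.radius_px, diameter_nm=rec.diameter_nm,
                score=rec.score, source=rec.source,
                border_truncated=rec.border_truncated,
                excluded=True, exclusion_reason=reason))
        else:
            out.append(rec)
    return out


# ---------------------------------------------------------------------------
# distributions


def size_distribution(records: list, class_name: str = None,
                      bin_width_nm: float = 10.0) -> SizeDistribution:
    """Median, sample SD (n-1), count and half-open-bin histogram of the
    non-excluded records' diameters.

    Empty input gives count 0 with the median flagged undefined; a
    single diameter gives SD 0 with the SD flagged undefined.
    """
    use = [r for r in records if not r.excluded
           and (class_name is None or r.class_name == class_name)]
    diameters = np.array([r.diameter_nm for r in use], dtype=np.float64)
    name = class_name or (use[0].class_name if use else "all")
    n = len(diameters)
    if n == 0:
        return SizeDistribution(class_name=name, diameters=diameters,
                                median=float("nan"), sd=0.0, count=0,
                                bin_edges=np.array([0.0, bin_width_nm]),
                                bin_counts=np.array([0]),
                                sd_defined=False, median_defined=False)
    median = float(np.median(diameters))
    if n == 1:
        sd, sd_defined = 0.0, False
    else:
        sd, sd_defined = float(np.std(diameters, ddof=1)), True
    lo = math.floor(diameters.min() / bin_width_nm) * bin_width_nm
    hi = math.floor(diameters.max() / bin_width_nm) * bin_width_nm + bin_width_nm
    edges = np.arange(lo, hi + bin_width_nm / 2, bin_width_nm)
    counts, _ = np.histogram(diameters, bins=edges)
    return SizeDistribution(class_name=name, diameters=diameters, median=median,
                            sd=sd, count=n, bin_edges=edges, bin_counts=counts,
                            sd_defined=sd_defined)
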
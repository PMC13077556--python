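"""Core domain containers shared across the pipeline.

All physical lengths are nanometres; all coordinates are 0-based
``(row, col) = (y, x)`` pixels with pixel centers at integer positions.
Radii are kept in pixels internally and converted to nm only at
reporting boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "AcquisitionMetadata",
    "Micrograph",
    "PreprocessConfig",
    "SegmentationMask",
    "HoughConfig",
    "ParticleRecord",
    "SizeDistribution",
    "MatchResult",
]


@dataclass(frozen=True)
class AcquisitionMetadata:
    """Imaging conditions attached to a micrograph.

    ``total_dose`` (e/A^2) is the product of dose rate and exposure when
    both are given; the constructor enforces that consistency.
    """

    magnification: Optional[float] = None
    dose_rate: Optional[float] = None  # e/A^2/s
    exposure: Optional[float] = None  # s
    total_dose: Optional[float] = None  # e/A^2
    defocus: Optional[float] = None  # um, negative = underfocus
    detector: Optional[str] = None  # "DED" or "CCD"

    def __post_init__(self):
        if self.dose_rate is not None and self.exposure is not None:
            expected = self.dose_rate * self.exposure
            if self.total_dose is None:
                object.__setattr__(self, "total_dose", expected)
            elif not math.isclose(self.total_dose, expected, rel_tol=0.05):
                raise ValueError(
                    f"total_dose={self.total_dose} inconsistent with "
                    f"dose_rate*exposure={expected}"
                )
        if self.detector is not None and self.detector not in ("DED", "CCD"):
            raise ValueError(f"detector must be 'DED' or 'CCD', got {self.detector!r}")


@dataclass
class Micrograph:
    """A 2-D intensity grid with a physical pixel size in nm/pixel."""

    pixels: np.ndarray
    pixel_size: float  # nm / pixel
    metadata: Optional[AcquisitionMetadata] = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {self.pixels.shape}")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels contain non-finite values")

    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray, pixel_size: Optional[float] = None) -> "Micrograph":
        return Micrograph(
            pixels=pixels,
            pixel_size=self.pixel_size if pixel_size is None else pixel_size,
            metadata=self.metadata,
        )


@dataclass(frozen=True)
class PreprocessConfig:
    """Image-conditioning parameters.

    ``filter_large``/``filter_small`` are characteristic feature sizes in
    pixels bounding the bandpass passband (default 50/2, the setting used
    for lipoprotein detection); ``bin_factor`` is the integer downsampling
    factor applied before Hough sizing (default 4, taking 0.55 nm pixels
    to 2.2 nm).
    """

    filter_large: float = 50.0
    filter_small: float = 2.0
    bin_factor: int = 4
    normalize_percentiles: tuple = (0.1, 99.9)

    def __post_init__(self):
        if not (self.filter_large > self.filter_small > 0):
            raise ValueError(
                f"need filter_large > filter_small > 0, got "
                f"{self.filter_large}, {self.filter_small}"
            )
        if self.bin_factor not in (1, 2, 4, 8):
            raise ValueError(f"bin_factor must be one of 1,2,4,8, got {self.bin_factor}")
        lo, hi = self.normalize_percentiles
        if not (0 <= lo < hi <= 100):
            raise ValueError(f"bad percentiles {self.normalize_percentiles}")


@dataclass
class SegmentationMask:
    """Per-class probability + binary mask aligned to a micrograph."""

    class_name: str
    probability: np.ndarray  # float in [0,1], same shape as source
    threshold: float = 0.5
    binary: np.ndarray = None  # derived unless supplied

    def __post_init__(self):
        self.probability = np.asarray(self.probability, dtype=float)
        if self.probability.ndim != 2:
            raise ValueError("probability grid must be 2-D")
        if self.probability.min() < 0 or self.probability.max() > 1:
            raise ValueError("probabilities must lie in [0,1]")
        if self.binary is None:
            self.binary = self.probability >= self.threshold
        else:
            self.binary = np.asarray(self.binary).astype(bool)
            if self.binary.shape != self.probability.shape:
                raise ValueError("binary and probability shapes differ")

    @property
    def shape(self) -> tuple:
        return self.probability.shape

    @classmethod
    def from_binary(cls, class_name: str, binary: np.ndarray, threshold: float = 0.5):
        binary = np.asarray(binary).astype(bool)
        return cls(class_name=class_name, probability=binary.astype(float),
                   threshold=threshold, binary=binary)


@dataclass(frozen=True)
class HoughConfig:
    """Circle-transform parameters.

    Radii are in (binned) pixels. The defaults follow the published
    protocol: radii 6..100 px, kept above a normalized vote score of 0.8
    for complete circles and 0.5 for (possibly partial) rings. At the
    default 2.2 nm binned pixel these radii correspond to diameters of
    26.4-440 nm.
    """

    r_min: int = 6
    r_max: int = 100
    score_threshold_circles: float = 0.8
    score_threshold_rings: float = 0.5

    def __post_init__(self):
        if not (0 < self.r_min < self.r_max):
            raise ValueError(f"need 0 < r_min < r_max, got {self.r_min}, {self.r_max}")
        for t in (self.score_threshold_circles, self.score_threshold_rings):
            if not (0 < t <= 1):
                raise ValueError(f"thresholds must be in (0,1], got {t}")

    def diameter_bounds_nm(self, pixel_size: float) -> tuple:
        """Smallest/largest reportable particle diameter in nm."""
        return (2.0 * self.r_min * pixel_size, 2.0 * self.r_max * pixel_size)


@dataclass
class ParticleRecord:
    """One detected object.

    ``source`` records how the size was measured: ``hough_ring`` /
    ``hough_circle`` give diameter = 2 * radius_px * pixel_size, while
    ``area`` gives the area-equivalent diameter d = 2*sqrt(A/pi).
    """

    class_name: str
    y: float
    x: float
    radius_px: float
    diameter_nm: float
    score: float
    source: str  # hough_ring | hough_circle | area
    border_truncated: bool = False
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self):
        if self.source not in ("hough_ring", "hough_circle", "area"):
            raise ValueError(f"unknown source {self.source!r}")


@dataclass
class SizeDistribution:
    """Median / SD / count / histogram over a set of particle diameters."""

    class_name: str
    diameters: np.ndarray  # nm
    median: float
    sd: float
    count: int
    bin_edges: np.ndarray
    bin_counts: np.ndarray
    sd_defined: bool = True
    median_defined: bool = True

    def as_dict(self) -> dict:
        return {
            "class_name": self.class_name,
            "median_nm": None if not self.median_defined else float(self.median),
            "sd_nm": float(self.sd),
            "sd_defined": bool(self.sd_defined),
            "count": int(self.count),
            "bin_edges_nm": [float(v) for v in self.bin_edges],
            "bin_counts": [int(v) for v in self.bin_counts],
        }


@dataclass
class MatchResult:
    """Greedy matching of predicted against ground-truth particles."""

    pairs: list  # (truth_index, pred_index)
    tp: int
    fp: int
    fn: int
    diameter_errors: np.ndarray  # nm, predicted - true, one per pair
    truth_classes: list = field(default_factory=list)  # class per pair

    def __post_init__(self):
        if self.tp != len(self.pairs):
            raise ValueError("tp must equal number of matched pairs")


def records_replace(record: ParticleRecord, **kw) -> ParticleRecord:
    """Functional update helper (records are plain dataclasses)."""
    return replace(record, **kw)
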
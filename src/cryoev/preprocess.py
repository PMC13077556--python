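"""Image conditioning applied before annotation/prediction and sizing.

Four operations: 8-bit percentile normalization, frequency-domain
bandpass filtering (default passband: feature sizes 2-50 px), mean-pool
binning (default 4x, taking 0.55 nm pixels to 2.2 nm), and 3x3 median
despeckling of masks/images.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .types import Micrograph, PreprocessConfig

__all__ = ["normalize_to_8bit", "bandpass_filter", "bin_image", "despeckle"]


def normalize_to_8bit(m: Micrograph, percentiles: tuple = (0.1, 99.9)) -> Micrograph:
    """Clip at intensity percentiles and map linearly to [0, 255].

    A constant image has no dynamic range; it maps to flat mid-grey
    (128) with a warning rather than raising.
    """
    lo_p, hi_p = percentiles
    if not (0 <= lo_p < hi_p <= 100):
        raise ValueError(f"bad percentiles {percentiles}")
    px = np.asarray(m.pixels, dtype=np.float64)
    lo, hi = np.percentile(px, [lo_p, hi_p])
    if hi <= lo:
        warnings.warn("constant image: normalizing to flat mid-grey", stacklevel=2)
        out = np.full(px.shape, 128.0)
    else:
        out = (np.clip(px, lo, hi) - lo) / (hi - lo) * 255.0
    return m.with_pixels(out)


def _bandpass_transfer(shape: tuple, filter_large: float, filter_small: float) -> np.ndarray:
    """Gaussian band mask over rfft2 frequencies.

    Characteristic feature size is treated as a spatial period: periods
    above ``filter_large`` px (including DC) and below ``filter_small``
    px are attenuated >= 90%, the geometric mid-band is preserved
    >= 80% in amplitude. The exponents (2 and 3) are fixed so those
    bounds hold for the default 50/2 setting.
    """
    h, w = shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.rfftfreq(w)[None, :]
    f = np.hypot(fy, fx)
    f_lo = 1.0 / filter_large
    f_hi = 1.0 / filter_small
    high_pass = 1.0 - np.exp(-2.0 * (f / f_lo) ** 2)
    low_pass = np.exp(-3.0 * (f / f_hi) ** 2)
    transfer = high_pass * low_pass
    transfer[0, 0] = 0.0  # exact DC removal
    return transfer


def bandpass_filter(m: Micrograph, cfg: PreprocessConfig = None, *,
                    filter_large: float = None, filter_small: float = None) -> Micrograph:
    """Suppress background variations and single-pixel noise.

    Output is zero-mean (DC removed); re-offsetting for 8-bit display is
    a separate step (`normalize_to_8bit`). Linear in its input.
    """
    if cfg is not None:
        filter_large = cfg.filter_large
        filter_small = cfg.filter_small
    if filter_large is None or filter_small is None:
        raise ValueError("provide cfg or both filter sizes")
    if not (filter_large > filter_small > 0):
        raise ValueError("need filter_large > filter_small > 0")
    if filter_large >= min(m.shape):
        raise ValueError(
            f"filter_large={filter_large} must be smaller than the image "
            f"(min dim {min(m.shape)})")
    px = np.asarray(m.pixels, dtype=np.float64)
    transfer = _bandpass_transfer(px.shape, filter_large, filter_small)
    out = np.fft.irfft2(np.fft.rfft2(px) * transfer, s=px.shape)
    return m.with_pixels(out)


def bin_image(m: Micrograph, factor: int) -> Micrograph:
    """Mean-pool ``factor x factor`` blocks; pixel size scales by ``factor``.

    Dimensions are cropped down to multiples of the factor (crop, not
    pad). The mean intensity over the cropped region is conserved
    exactly, and a feature at (y, x) maps to (y/factor, x/factor).
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError(f"factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return m.with_pixels(np.asarray(m.pixels, dtype=np.float64).copy())
    h, w = m.shape
    if factor > h or factor > w:
        raise ValueError(f"factor {factor} exceeds image dimensions {m.shape}")
    hc, wc = (h // factor) * factor, (w // factor) * factor
    px = np.asarray(m.pixels, dtype=np.float64)[:hc, :wc]
    out = px.reshape(hc // factor, factor, wc // factor, factor).mean(axis=(1, 3))
    return m.with_pixels(out, pixel_size=m.pixel_size * factor)


def despeckle(mask_or_image: np.ndarray) -> np.ndarray:
    """3x3 median filter: removes isolated single-pixel foreground while
    leaving the interior of solid regions (>= 3x3) unchanged.

    Accepts a binary mask (returned as bool) or a greyscale image
    (returned as float of the same values' dtype behaviour).
    """
    arr = np.asarray(mask_or_image)
    if arr.ndim != 2:
        raise ValueError("despeckle expects a 2-D array")
    if arr.dtype == bool:
        return ndimage.median_filter(arr.astype(np.uint8), size=3,
                                     mode="constant", cval=0).astype(bool)
    return ndimage.median_filter(arr, size=3, mode="nearest")
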
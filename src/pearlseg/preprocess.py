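"""Preprocessing of backlit grayscale images into clean binary object masks.

Backlit illumination renders pearls (or any opaque near-convex objects) as
dark silhouettes on a bright field.  The cleanup chain is: global histogram
equalization, Gaussian smoothing, Otsu thresholding with the dark side taken
as foreground, and a morphological open/close with linear structuring
elements followed by hole filling.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "equalize_histogram",
    "gaussian_smooth",
    "otsu_threshold",
    "binarize_otsu",
    "morphological_clean",
]


def as_uint8(img: np.ndarray) -> np.ndarray:
    """Coerce an intensity raster to a 2-D uint8 array in [0, 255]."""
    a = np.asarray(img)
    if a.ndim != 2 or a.size == 0:
        raise ValueError("expected a non-empty 2-D grayscale image")
    if a.dtype == np.uint8:
        return a
    return np.clip(np.rint(np.asarray(a, dtype=np.float64)), 0, 255).astype(np.uint8)


def equalize_histogram(img: np.ndarray) -> np.ndarray:
    """Global cumulative-distribution histogram equalization.

    Uses the classical integer CDF mapping
    ``v -> round((cdf(v) - cdf_min) / (N - cdf_min) * 255)`` so that the
    darkest occupied level maps to 0 and the brightest to 255.  A single-level
    image is returned unchanged (the mapping is degenerate).
    """
    a = as_uint8(img)
    hist = np.bincount(a.ravel(), minlength=256)
    cdf = np.cumsum(hist)
    cdf_min = int(cdf[np.nonzero(hist)[0][0]])
    total = int(a.size)
    if total == cdf_min:  # one gray level only
        return a.copy()
    lut = np.rint((cdf - cdf_min) / (total - cdf_min) * 255.0)
    lut = np.clip(lut, 0, 255).astype(np.uint8)
    return lut[a]


def gaussian_smooth(img: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Separable Gaussian smoothing with reflective border handling.

    Returns float64; downstream thresholding re-quantizes.  Reflection avoids
    the dark frame a zero-padded convolution would stamp onto a bright field.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    a = np.asarray(as_uint8(img), dtype=np.float64)
    return ndimage.gaussian_filter(a, sigma=sigma, mode="reflect")


def otsu_threshold(img: np.ndarray) -> int:
    """Integer threshold maximizing the between-class variance.

    The two classes are ``{v < t}`` and ``{v >= t}`` for t in [1, 255]; the
    smallest maximizer is returned.  An image with fewer than two occupied
    gray levels yields 0 (no pixel falls below the threshold).
    """
    a = as_uint8(img)
    hist = np.bincount(a.ravel(), minlength=256).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        return 0
    n = hist.sum()
    levels = np.arange(256, dtype=np.float64)
    cum = np.cumsum(hist)
    cum_val = np.cumsum(hist * levels)
    w0 = cum[:-1]            # pixels with v < t, t = 1..255
    w1 = n - w0
    valid = (w0 > 0) & (w1 > 0)
    mu0 = np.divide(cum_val[:-1], w0, out=np.zeros(255), where=valid)
    mu1 = np.divide(cum_val[-1] - cum_val[:-1], w1, out=np.zeros(255), where=valid)
    sigma_b = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    return int(np.argmax(sigma_b)) + 1


def binarize_otsu(
    img: np.ndarray, dark_objects: bool = True, threshold: int | None = None
) -> np.ndarray:
    """Binarize with Otsu's threshold; foreground = object pixels.

    Under backlighting the objects are dark, so by default pixels strictly
    below the threshold become foreground.  Set ``dark_objects=False`` for
    inverted (bright-object) inputs.
    """
    a = as_uint8(img)
    t = otsu_threshold(a) if threshold is None else int(threshold)
    return a < t if dark_objects else a >= t


def morphological_clean(
    mask: np.ndarray, element_length: int = 3, fill_holes: bool = True
) -> np.ndarray:
    """Open then close with horizontal and vertical line elements, fill holes.

    The linear elements knock off single-pixel contour roughness in both
    orientations; hole filling guarantees simply connected regions, which the
    diameter measurement downstream requires.
    """
    if element_length < 1 or element_length % 2 == 0:
        raise ValueError("element_length must be odd and >= 1")
    m = np.asarray(mask, dtype=bool)
    if m.ndim != 2:
        raise ValueError("mask must be 2-D")
    if element_length > 1:
        horiz = np.ones((1, element_length), dtype=bool)
        vert = np.ones((element_length, 1), dtype=bool)
        m = ndimage.binary_opening(ndimage.binary_opening(m, horiz), vert)
        m = ndimage.binary_closing(ndimage.binary_closing(m, horiz), vert)
    if fill_holes:
        m = ndimage.binary_fill_holes(m)
    return m
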
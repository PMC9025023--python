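"""Per-object diameter measurement and roundness grading.

The shape parameter is the diameter-difference percentage

    X = (d_max - d_min) / d_mean * 100

over the chord-through-centroid diameters d_i measured at every contour
pixel.  Grades follow the freshwater-pearl roundness bands of
GB/T 18781-2008: X <= 3.0 perfect circle (A1), <= 8.0 circle (A2),
<= 12.0 near circle (A3), <= 20.0 ellipse (B), beyond that ungraded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure

from . import regions as regions_mod

__all__ = [
    "GRADE_BANDS",
    "ShapeReport",
    "measure_diameters",
    "shape_parameter",
    "grade",
    "grade_objects",
]

#: (upper X bound, label), evaluated first-match
GRADE_BANDS: tuple[tuple[float, str], ...] = (
    (3.0, "A1"),
    (8.0, "A2"),
    (12.0, "A3"),
    (20.0, "B"),
)

UNGRADED = "ungraded"


@dataclass
class ShapeReport:
    label: int
    d_max_mm: float
    d_min_mm: float
    d_mean_mm: float
    X_percent: float
    grade: str
    diameters_mm: np.ndarray


def measure_diameters(
    contour: np.ndarray,
    centroid,
    mm_per_px: float = 1.0 / 20.0,
    smooth_window: int = 5,
) -> np.ndarray:
    """Chord-through-centroid diameter at every contour pixel.

    For contour pixel i, d_i is the distance to the contour pixel whose
    direction from the centroid is closest to antipodal.  A circular moving
    average of ``smooth_window`` samples over the ordered contour suppresses
    the +-1 px quantization jitter of the digital boundary before the
    max/min are taken downstream; the returned array keeps one entry per
    contour pixel.

    Raises
    ------
    ValueError
        If the centroid does not lie inside the contour (the antipodal ray
        is then undefined for some pixels).
    """
    pts = np.asarray(contour, dtype=np.float64)
    if pts.ndim != 2 or len(pts) < 3:
        raise ValueError("need a closed contour of at least 3 points")
    c = np.asarray(centroid, dtype=np.float64)
    v = pts - c
    phi = np.arctan2(v[:, 1], v[:, 0])
    # winding number of the closed contour about the centroid: +-1 inside, 0 outside
    dphi = np.angle(np.exp(1j * np.diff(np.concatenate([phi, phi[:1]]))))
    if abs(round(dphi.sum() / (2 * np.pi))) != 1:
        raise ValueError("centroid lies outside the contour")
    order = np.argsort(phi)
    sphi = phi[order]

    target = np.mod(phi + np.pi + np.pi, 2 * np.pi) - np.pi  # wrap to (-pi, pi]
    pos = np.searchsorted(sphi, target)
    n = len(pts)
    lo = (pos - 1) % n
    hi = pos % n
    d_lo = np.abs(np.angle(np.exp(1j * (sphi[lo] - target))))
    d_hi = np.abs(np.angle(np.exp(1j * (sphi[hi] - target))))
    j = np.where(d_lo <= d_hi, order[lo], order[hi])
    # +1 px: a chord between boundary-pixel centers spans n-1 px of an
    # n-px-wide object (half a pixel is cut off at each end)
    d = (np.linalg.norm(pts - pts[j], axis=1) + 1.0) * float(mm_per_px)

    if smooth_window and smooth_window > 1:
        w = int(smooth_window)
        kernel = np.ones(w) / w
        d = np.convolve(np.concatenate([d[-(w - 1):], d, d[: w - 1]]), kernel, mode="same")[
            w - 1 : w - 1 + n
        ]
    return d


def shape_parameter(diameters: np.ndarray, mean_mode: str = "contour") -> float:
    """Diameter-difference percentage X = (d_max - d_min) / d_mean * 100.

    ``mean_mode="contour"`` uses mean(d_i); ``"extremes"`` uses
    (d_max + d_min) / 2.  The two agree for circles.
    """
    d = np.asarray(diameters, dtype=np.float64)
    if d.size < 3:
        raise ValueError("need at least 3 diameters")
    d_max, d_min = float(d.max()), float(d.min())
    if mean_mode == "contour":
        d_mean = float(d.mean())
    elif mean_mode == "extremes":
        d_mean = (d_max + d_min) / 2.0
    else:
        raise ValueError(f"unknown mean_mode {mean_mode!r}")
    if d_mean == 0:
        raise ValueError("zero mean diameter")
    return (d_max - d_min) / d_mean * 100.0


def grade(x_percent: float, bands=GRADE_BANDS) -> str:
    """Map X to its roundness grade; bands are inclusive upper bounds.

    A small epsilon keeps values that are equal to a band limit up to
    floating-point round-off inside the band.
    """
    if x_percent < 0:
        raise ValueError("X must be non-negative")
    for bound, label in bands:
        if x_percent <= bound + 1e-9:
            return label
    return UNGRADED


def grade_objects(
    labels: np.ndarray,
    mm_per_px: float = 1.0 / 20.0,
    mean_mode: str = "contour",
    smooth_window: int = 5,
) -> pd.DataFrame:
    """Measure and grade every labeled object.

    Returns one row per label: d_max_mm, d_min_mm, d_mean_mm, X_percent,
    grade, plus the object centroid for downstream matching.
    """
    rows = []
    for p in measure.regionprops(np.asarray(labels)):
        contour = regions_mod.trace_contour(labels, p.label)
        d = measure_diameters(contour, p.centroid, mm_per_px, smooth_window)
        x = shape_parameter(d, mean_mode=mean_mode)
        d_max, d_min = float(d.max()), float(d.min())
        d_mean = float(d.mean()) if mean_mode == "contour" else (d_max + d_min) / 2
        rows.append(
            {
                "label": p.label,
                "centroid_row": float(p.centroid[0]),
                "centroid_col": float(p.centroid[1]),
                "d_max_mm": d_max,
                "d_min_mm": d_min,
                "d_mean_mm": d_mean,
                "X_percent": x,
                "grade": grade(x),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "label",
            "centroid_row",
            "centroid_col",
            "d_max_mm",
            "d_min_mm",
            "d_mean_mm",
            "X_percent",
            "grade",
        ],
    )
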
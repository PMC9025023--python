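"""Connected-domain analysis: labeling, area ratios K_n, contact flags, contours.

A batch image yields one connected domain per isolated object and one per
cluster of mutually touching objects.  Because a touching cluster is at
least twice the area of a single object, the ratio of each domain's area to
the smallest domain's area (K_n = S_n / S_min) separates singles (K near 1)
from contact clusters (K above a threshold, 1.50 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from skimage import measure

__all__ = [
    "RegionTable",
    "label_connected",
    "area_ratios",
    "select_contact_regions",
    "trace_contour",
]

#: default speckle floor in pixels; real objects are thousands of pixels
MIN_REGION_AREA = 50


@dataclass
class RegionTable:
    """Labeled connected domains of a binary mask.

    Attributes
    ----------
    labels : ndarray of int
        Label image; 0 is background, regions are 1..n.
    table : DataFrame
        One row per region: ``label, area_px, centroid_row, centroid_col``
        plus ``K`` after :func:`area_ratios` and ``is_contact`` after
        :func:`select_contact_regions`.
    """

    labels: np.ndarray
    table: pd.DataFrame

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.to_csv(path, index=False, float_format="%.2f")


def label_connected(mask: np.ndarray, min_area: int = MIN_REGION_AREA) -> RegionTable:
    """8-connected component labeling with a small-speckle floor.

    Regions below ``min_area`` pixels are discarded (set to background) and
    surviving regions are renumbered 1..n in raster order.

    Raises
    ------
    ValueError
        If the mask contains no foreground pixel at all.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("mask has no foreground pixels")
    lbl = measure.label(m, connectivity=2)
    areas = np.bincount(lbl.ravel())
    areas[0] = 0
    keep = np.nonzero(areas >= min_area)[0]
    remap = np.zeros(areas.size, dtype=np.int32)
    remap[keep] = np.arange(1, keep.size + 1)
    lbl = remap[lbl]
    rows = []
    for p in measure.regionprops(lbl):
        rows.append(
            {
                "label": p.label,
                "area_px": int(p.area),
                "centroid_row": float(p.centroid[0]),
                "centroid_col": float(p.centroid[1]),
            }
        )
    table = pd.DataFrame(rows, columns=["label", "area_px", "centroid_row", "centroid_col"])
    return RegionTable(labels=lbl, table=table)


def area_ratios(rt: RegionTable, reference_area: float | None = None) -> RegionTable:
    """Compute K_n = S_n / S_min for every region, rounded to 2 decimals.

    ``reference_area`` substitutes for S_min when the caller knows that no
    isolated object is present (all regions are clusters); otherwise S_min is
    the smallest labeled area and the smallest region has K = 1.00 exactly.
    """
    if len(rt.table) == 0:
        raise ValueError("no regions to ratio")
    s_min = float(reference_area) if reference_area else float(rt.table["area_px"].min())
    if s_min <= 0:
        raise ValueError("reference area must be positive")
    table = rt.table.copy()
    table["K"] = (table["area_px"] / s_min).round(2)
    return replace(rt, table=table)


def select_contact_regions(rt: RegionTable, k_threshold: float = 1.50) -> RegionTable:
    """Flag contact clusters: is_contact = (K > k_threshold), strictly."""
    if "K" not in rt.table.columns:
        raise ValueError("run area_ratios first")
    table = rt.table.copy()
    table["is_contact"] = table["K"] > k_threshold
    return replace(rt, table=table)


# clockwise Moore neighborhood in (row, col) screen coordinates, from North
_MOORE = (
    (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1),
)
_DIR_INDEX = {d: i for i, d in enumerate(_MOORE)}


def trace_contour(mask: np.ndarray, label: int | None = None) -> np.ndarray:
    """Moore-neighbor boundary trace of one region, clockwise.

    Parameters
    ----------
    mask : ndarray
        Either a boolean mask of a single region, or an integer label image
        (then ``label`` selects the region).
    label : int, optional
        Region id when ``mask`` is a label image.

    Returns
    -------
    ndarray of shape (n, 2)
        Ordered closed boundary pixels as (row, col); the first point is the
        topmost-then-leftmost boundary pixel, the last point is an 8-neighbor
        of the first, and no point repeats.
    """
    a = np.asarray(mask)
    if a.dtype == bool:
        region = a
    else:
        if label is None:
            raise ValueError("label required for a label image")
        region = a == label
    if not region.any():
        raise ValueError(f"region {label!r} not found")

    pad = np.pad(region, 1)
    rows, cols = np.nonzero(pad)
    start = (int(rows.min()), int(cols[rows == rows.min()].min()))

    # clockwise walk, stopping when the trace re-enters the start pixel
    p = start
    b = (start[0], start[1] - 1)  # West neighbor, background by choice of start
    contour: list[tuple[int, int]] = []
    max_steps = 4 * int(region.sum()) + 8
    for _ in range(max_steps):
        contour.append(p)
        db = _DIR_INDEX[(b[0] - p[0], b[1] - p[1])]
        nxt = None
        for i in range(1, 9):
            d = _MOORE[(db + i) % 8]
            q = (p[0] + d[0], p[1] + d[1])
            if pad[q]:
                nxt = q
                prev = _MOORE[(db + i - 1) % 8]
                b = (p[0] + prev[0], p[1] + prev[1])
                break
        if nxt is None or nxt == start:  # isolated pixel, or loop closed
            break
        p = nxt
    pts = np.asarray(contour, dtype=np.intp) - 1  # undo padding offset
    return pts
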
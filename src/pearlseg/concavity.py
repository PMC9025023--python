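"""Concave-point detection, pit-pair matching, and splitting of tangent objects.

Where two convex objects touch, the shared boundary of the merged region
forms a narrow neck whose two entrances are sharp inward notches ("pits").
The pit angle at contour point p_k is the included angle between the chords
to the points ``step`` positions before and after it (law of cosines on the
three chord lengths).  Points with an angle below a threshold (60 degrees by
default) are candidate pits; a matching stage pairs the two pits of one neck
and validates the pair by sampling the source image along the perpendicular
bisector of the connecting segment — a true neck is object-gray throughout.
Validated pairs are cut with a one-pixel digital segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.cluster import KMeans

from . import preprocess, regions
from .config import RunConfig

__all__ = [
    "AnglePoint",
    "PitPair",
    "UnsplittableRegionError",
    "vertex_angle",
    "detect_candidates",
    "match_pits",
    "split_region",
    "segment_scene",
    "SegmentationResult",
]


@dataclass(frozen=True)
class AnglePoint:
    """Contour point with its three-point included angle."""

    index: int
    point: tuple[int, int]
    angle_deg: float
    is_candidate: bool


@dataclass(frozen=True)
class PitPair:
    """Two matched concave points delimiting one contact neck."""

    a: tuple[int, int]
    b: tuple[int, int]

    @property
    def dist_px(self) -> float:
        return float(np.hypot(self.a[0] - self.b[0], self.a[1] - self.b[1]))

    @property
    def midpoint(self) -> tuple[float, float]:
        return ((self.a[0] + self.b[0]) / 2.0, (self.a[1] + self.b[1]) / 2.0)


class UnsplittableRegionError(RuntimeError):
    """No acceptable pit pair exists even after relaxing the angle threshold."""


def vertex_angle(p_prev, p, p_next) -> float:
    """Included angle at ``p`` between segments to ``p_prev`` and ``p_next``.

    Computed by the law of cosines on the three chord lengths; returns
    degrees in (0, 180].  Raises ValueError on coincident points.
    """
    p_prev = np.asarray(p_prev, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    p_next = np.asarray(p_next, dtype=np.float64)
    s_next = np.linalg.norm(p_next - p)
    s_prev = np.linalg.norm(p_prev - p)
    s_opp = np.linalg.norm(p_next - p_prev)
    if s_next == 0 or s_prev == 0:
        raise ValueError("coincident points have no included angle")
    cos_t = (s_next**2 + s_prev**2 - s_opp**2) / (2.0 * s_next * s_prev)
    return float(np.degrees(np.arccos(np.clip(cos_t, -1.0, 1.0))))


def detect_candidates(
    contour: np.ndarray,
    step: int = 2,
    angle_threshold_deg: float = 60.0,
) -> list[AnglePoint]:
    """Angle model over a closed contour; candidates are sharp notches.

    For every contour index k the included angle between the chords to the
    points ``step`` positions before and after (cyclically) is computed.
    Indices with angle at or below the threshold form candidate runs; each
    run is collapsed to its minimum-angle point so that one physical pit
    yields one candidate.  (The comparison is inclusive: on a digital
    contour with a 2-px step the sharpest attainable notch angle is often
    exactly 90 degrees, which must remain reachable by the adaptive
    relaxation cap.)
    """
    pts = np.asarray(contour, dtype=np.float64)
    n = len(pts)
    if n <= 2 * step:
        raise ValueError("contour too short for the angle step")
    u = np.roll(pts, step, axis=0) - pts
    v = np.roll(pts, -step, axis=0) - pts
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    nb = np.linalg.norm(np.roll(pts, -step, axis=0) - np.roll(pts, step, axis=0), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_t = (nu**2 + nv**2 - nb**2) / (2.0 * nu * nv)
    angles = np.degrees(np.arccos(np.clip(cos_t, -1.0, 1.0)))
    angles[(nu == 0) | (nv == 0)] = 180.0

    raw = angles <= angle_threshold_deg
    keep = np.zeros(n, dtype=bool)
    if raw.all():
        keep[int(np.argmin(angles))] = True
    elif raw.any():
        # rotate so index 0 is not a candidate, then split into runs
        shift = int(np.argmin(raw))  # first False
        rot = np.roll(raw, -shift)
        idx = np.nonzero(rot)[0]
        breaks = np.nonzero(np.diff(idx) > 1)[0]
        for run in np.split(idx, breaks + 1):
            orig = (run + shift) % n
            keep[orig[int(np.argmin(angles[orig]))]] = True

    out = []
    ipts = np.asarray(contour)
    for k in range(n):
        out.append(
            AnglePoint(
                index=k,
                point=(int(ipts[k, 0]), int(ipts[k, 1])),
                angle_deg=float(angles[k]),
                is_candidate=bool(keep[k]),
            )
        )
    return out


def _supercover_line(a, b) -> tuple[np.ndarray, np.ndarray]:
    """Bresenham segment thickened at diagonal steps.

    Removing the returned pixels from an 8-connected region actually
    disconnects the two sides (a plain Bresenham line leaves diagonal
    bridges).
    """
    from skimage.draw import line

    rr, cc = line(int(a[0]), int(a[1]), int(b[0]), int(b[1]))
    extra_r, extra_c = [], []
    for k in range(1, len(rr)):
        if rr[k] != rr[k - 1] and cc[k] != cc[k - 1]:
            extra_r.append(rr[k - 1])
            extra_c.append(cc[k])
    if extra_r:
        rr = np.concatenate([rr, extra_r])
        cc = np.concatenate([cc, extra_c])
    return rr, cc


def _bisector_samples(a, b, shape) -> np.ndarray:
    """Integer points of the perpendicular bisector strictly inside the
    circle whose diameter is the segment a-b."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    mid = (a + b) / 2.0
    v = b - a
    r = np.linalg.norm(v) / 2.0
    if r < 1.0:
        pts = np.rint(mid)[None, :]
    else:
        w = np.array([-v[1], v[0]]) / (2.0 * r)
        ts = np.arange(-r + 0.5, r, 0.5)
        pts = np.unique(np.rint(mid + ts[:, None] * w), axis=0)
    pts = pts.astype(np.intp)
    ok = (
        (pts[:, 0] >= 0)
        & (pts[:, 0] < shape[0])
        & (pts[:, 1] >= 0)
        & (pts[:, 1] < shape[1])
    )
    return pts[ok]


def _pair_order(coords: np.ndarray, seed: int) -> list[tuple[int, int]]:
    """Candidate pair priority: 2-means cross-class pairs by distance, then
    same-class pairs by distance.

    Initialization is deterministic: the two mutually farthest candidates.
    With exactly two candidates the clustering is trivially {A}, {B}.
    """
    m = len(coords)
    if m == 2:
        return [(0, 1)]
    d = squareform(pdist(coords))
    i0, j0 = np.unravel_index(np.argmax(d), d.shape)
    km = KMeans(n_clusters=2, init=coords[[i0, j0]], n_init=1, random_state=seed)
    lab = km.fit_predict(coords)
    cross, same = [], []
    for i in range(m):
        for j in range(i + 1, m):
            (cross if lab[i] != lab[j] else same).append((d[i, j], i, j))
    cross.sort()
    same.sort()
    return [(i, j) for _, i, j in cross] + [(i, j) for _, i, j in same]


def _pair_is_valid(a, b, gray, threshold, region_mask, dist_bg, depth_gate, dark_objects):
    """Neck validation: the cut stays inside the region, is shallow relative
    to the region's inscribed radius, and the perpendicular-bisector samples
    are all object-gray."""
    if a == b:
        return False
    rr, cc = _supercover_line(a, b)
    inside = (
        (rr >= 0) & (rr < region_mask.shape[0]) & (cc >= 0) & (cc < region_mask.shape[1])
    )
    if not inside.all() or not region_mask[rr, cc].all():
        return False
    if dist_bg[rr, cc].max() > depth_gate:
        return False
    pts = _bisector_samples(a, b, gray.shape)
    if len(pts) == 0:
        return False
    vals = gray[pts[:, 0], pts[:, 1]]
    return bool((vals < threshold).all()) if dark_objects else bool((vals >= threshold).all())


def match_pits(
    candidates: list[AnglePoint] | None,
    contour: np.ndarray,
    gray: np.ndarray,
    region_mask: np.ndarray,
    *,
    threshold: int | None = None,
    step: int = 2,
    max_step: int = 8,
    angle_threshold_deg: float = 60.0,
    max_angle_deg: float = 90.0,
    angle_increment_deg: float = 5.0,
    dark_objects: bool = True,
    depth_gate_frac: float = 0.5,
    exclusion_radius: float = 3.0,
    seed: int = 0,
) -> list[PitPair]:
    """Match candidate pits into validated pairs, one per contact neck.

    Implements the adaptive matching loop: (1) 2-means clustering of the
    candidate coordinates into classes A and B; (2) cross-class pairs are
    examined in order of Euclidean distance; (3)-(6) each pair is accepted
    only if every sampled point of the perpendicular bisector, restricted to
    the circle whose diameter is the connecting segment, has object gray
    (below the binarization threshold of the source image); (7) if no pair is
    acceptable the candidate set is enlarged by relaxing the angle threshold
    in 5-degree increments up to ``max_angle_deg`` and matching restarts.

    Three safeguards extend the published steps. Pairs whose cut would run
    deeper into the region than ``depth_gate_frac`` times the maximum
    inscribed radius are rejected (a neck hugs the boundary; a chord through
    an object's core does not).  If every cross-class pair fails, same-class
    pairs are examined with the same validation, which recovers necks whose
    two pits were clustered together.  And because the included angle of a
    rounded notch is scale-dependent — a wide blunt neck can show no angle
    below 90 degrees at a 2-px baseline — the angle step itself is escalated
    from ``step`` up to ``max_step``.  The full (step, threshold) ladder is
    walked so every neck of a multi-contact cluster is found; each accepted
    cut leaves an exclusion zone scaled to its neck width, which prevents
    the same neck from being cut twice at a later rung.

    Raises
    ------
    UnsplittableRegionError
        If no acceptable pair exists even at the relaxed threshold cap.
    """
    gray = preprocess.as_uint8(gray)
    region_mask = np.asarray(region_mask, dtype=bool)
    t = preprocess.otsu_threshold(gray) if threshold is None else int(threshold)
    dist_bg = ndimage.distance_transform_edt(region_mask)
    depth_gate = depth_gate_frac * float(dist_bg.max())

    accepted: list[PitPair] = []
    # exclusion zones around accepted cuts: (segment pixels, radius); radius
    # scales with the neck width so the same neck cannot be cut twice at a
    # higher rung of the ladder
    zones: list[tuple[np.ndarray, float]] = []

    def excluded(pt) -> bool:
        return any(cdist([pt], px).min() <= rad for px, rad in zones)

    provided = candidates
    for cur_step in range(step, max(step, max_step) + 1):
        if len(contour) <= 2 * cur_step:
            break
        thr = float(angle_threshold_deg)
        while True:
            if provided is not None and cur_step == step and thr == angle_threshold_deg:
                apts = provided
            else:
                apts = detect_candidates(contour, step=cur_step, angle_threshold_deg=thr)
            cand = [p for p in apts if p.is_candidate and not excluded(p.point)]
            # greedily extract as many validated pairs as the candidate set holds
            while len(cand) >= 2:
                coords = np.asarray([p.point for p in cand], dtype=np.float64)
                hit = None
                for i, j in _pair_order(coords, seed):
                    a, b = cand[i].point, cand[j].point
                    mid = ((a[0] + b[0]) / 2.0, (a[1] + b[1]) / 2.0)
                    if excluded(mid):
                        continue
                    if _pair_is_valid(
                        a, b, gray, t, region_mask, dist_bg, depth_gate, dark_objects
                    ):
                        hit = (i, j)
                        break
                if hit is None:
                    break
                i, j = hit
                pair = PitPair(a=cand[i].point, b=cand[j].point)
                accepted.append(pair)
                rr, cc = _supercover_line(pair.a, pair.b)
                zones.append(
                    (
                        np.column_stack([rr, cc]),
                        max(exclusion_radius, 0.6 * pair.dist_px),
                    )
                )
                cand = [
                    p
                    for k, p in enumerate(cand)
                    if k not in (i, j) and not excluded(p.point)
                ]
            if thr >= max_angle_deg:
                break
            thr = min(thr + angle_increment_deg, max_angle_deg)
    if not accepted:
        raise UnsplittableRegionError(
            f"no valid pit pair up to step {max_step} at the {max_angle_deg:.0f} degree cap"
        )
    return accepted


def split_region(mask: np.ndarray, pairs: list[PitPair]) -> np.ndarray:
    """Cut each pit pair's connecting digital segment out of the mask.

    The segment pixels (Bresenham, thickened at diagonal steps so the cut
    really disconnects 8-connected foreground) are set to background; they
    are charged to neither resulting object.
    """
    out = np.asarray(mask, dtype=bool).copy()
    for pair in pairs:
        rr, cc = _supercover_line(pair.a, pair.b)
        if not out[rr, cc].all():
            raise ValueError("split segment leaves the foreground region")
        out[rr, cc] = False
    return out


@dataclass
class SegmentationResult:
    """End-to-end segmentation output of one scene."""

    labels: np.ndarray
    table: pd.DataFrame
    pit_pairs: list[PitPair] = field(default_factory=list)
    unsplittable: list[int] = field(default_factory=list)
    mask: np.ndarray | None = None          # binary mask before any split
    split_mask: np.ndarray | None = None    # binary mask after all splits
    threshold: int = 0
    smoothed: np.ndarray | None = None      # preprocessed intensity image

    @property
    def n_objects(self) -> int:
        return len(self.table)


def _region_signature(area: int, centroid: tuple[float, float]) -> tuple:
    return (int(area), int(round(centroid[0])), int(round(centroid[1])))


def segment_scene(gray: np.ndarray, config: RunConfig | None = None) -> SegmentationResult:
    """Full pipeline: preprocess, flag contact clusters, split them.

    The area-ratio contact test is re-run after every round of splits until
    every region satisfies K <= k_threshold or is flagged unsplittable, so
    multi-contact chains are resolved recursively.
    """
    cfg = config or RunConfig()
    eq = preprocess.equalize_histogram(gray)
    sm = preprocess.gaussian_smooth(eq, sigma=cfg.sigma)
    smu = preprocess.as_uint8(sm)
    t = preprocess.otsu_threshold(smu)
    mask0 = preprocess.binarize_otsu(smu, dark_objects=cfg.dark_objects, threshold=t)
    mask0 = preprocess.morphological_clean(mask0, element_length=cfg.element_length)
    mask = mask0.copy()

    pit_pairs: list[PitPair] = []
    failed: set[tuple] = set()
    rt = None
    for _ in range(cfg.max_split_rounds):
        rt = regions.label_connected(mask, min_area=cfg.min_area)
        if len(rt.table) == 0:
            break
        rt = regions.area_ratios(rt, reference_area=cfg.reference_area)
        rt = regions.select_contact_regions(rt, k_threshold=cfg.k_threshold)
        progress = False
        for row in rt.table.itertuples():
            if not row.is_contact:
                continue
            sig = _region_signature(row.area_px, (row.centroid_row, row.centroid_col))
            if sig in failed:
                continue
            region = rt.labels == row.label
            contour = regions.trace_contour(region)
            try:
                pairs = match_pits(
                    None,
                    contour,
                    smu,
                    region,
                    threshold=t,
                    step=cfg.step,
                    max_step=cfg.max_step,
                    angle_threshold_deg=cfg.angle_threshold_deg,
                    max_angle_deg=cfg.max_angle_deg,
                    angle_increment_deg=cfg.angle_increment_deg,
                    dark_objects=True,
                    depth_gate_frac=cfg.depth_gate_frac,
                    seed=cfg.seed,
                )
            except UnsplittableRegionError:
                failed.add(sig)
                continue
            mask = split_region(mask, pairs)
            pit_pairs.extend(pairs)
            progress = True
        if not progress:
            break

    rt = regions.label_connected(mask, min_area=cfg.min_area)
    rt = regions.area_ratios(rt, reference_area=cfg.reference_area)
    rt = regions.select_contact_regions(rt, k_threshold=cfg.k_threshold)
    unsplittable = [int(r.label) for r in rt.table.itertuples() if r.is_contact]
    return SegmentationResult(
        labels=rt.labels,
        table=rt.table,
        pit_pairs=pit_pairs,
        unsplittable=unsplittable,
        mask=mask0,
        split_mask=mask,
        threshold=t,
        smoothed=smu,
    )
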
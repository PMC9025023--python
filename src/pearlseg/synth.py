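"""Synthetic backlit scenes with instance-level ground truth.

The generator emulates the imaging geometry of a backlit batch-inspection
rig: dark, near-circular objects (discs or mild ellipses) on a bright
field, rendered with anti-aliased edges (4x supersampling then 8-bit
quantization) and mild Gaussian intensity noise.  Touching clusters are
built as chains of exactly tangent objects at controlled contact angles;
tangency is solved numerically so rotated ellipses touch without
overlapping.  Roundness grades are encoded by eccentricity: each grade's
diameter-difference percentage X is sampled from the interior of its band,
so the intended label is unambiguous under pixelation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from . import shape as shape_mod
from .config import RunConfig

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "generate_scene",
    "posture_sweep",
    "segmentation_stress",
    "SweepResult",
    "StressResult",
]

GRADE_X_RANGES = {  # interior of each X band, 10% margin per side
    "A1": (0.3, 2.7),
    "A2": (3.5, 7.5),
    "A3": (8.4, 11.6),
    "B": (12.8, 19.2),
}


@dataclass
class SceneSpec:
    """Declarative description of one synthetic scene.

    ``clusters`` lists cluster sizes (1 = isolated object).  ``grades`` is a
    single grade label applied to every object or one label per object in
    cluster order; ``axis_ratio`` overrides grade encoding with an explicit
    major/minor ratio (1.0 = ideal circle).  ``contact_angles`` optionally
    fixes, per cluster, the direction (degrees) along which each subsequent
    member touches the previous one; unspecified angles are drawn randomly.
    """

    clusters: tuple[int, ...] = (1,)
    grades: str | Sequence[str] = "A1"
    axis_ratio: float | None = None
    radius_px: float = 80.0
    radius_spread: float = 2.0
    contact_angles: Sequence[Sequence[float]] | None = None
    noise_sd: float = 5.0
    background: int = 230
    foreground: int = 25
    margin: int = 40
    max_row_width: int = 1500
    supersample: int = 4
    mm_per_px: float = 1.0 / 20.0
    seed: int = 0


@dataclass
class GroundTruth:
    """Instance label map plus per-object truth records."""

    labels: np.ndarray
    table: pd.DataFrame  # label, cluster, area_px, centroid, axes, X_true, grade
    contacts: list[dict] = field(default_factory=list)

    @property
    def n_objects(self) -> int:
        return len(self.table)


class _Ellipse:
    __slots__ = ("center", "a", "b", "psi")

    def __init__(self, center, a, b, psi):
        self.center = np.asarray(center, dtype=np.float64)
        self.a = float(a)
        self.b = float(b)
        self.psi = float(psi)

    def axes(self):
        e1 = np.array([np.cos(self.psi), np.sin(self.psi)])
        e2 = np.array([-np.sin(self.psi), np.cos(self.psi)])
        return e1, e2

    def implicit(self, pts: np.ndarray) -> np.ndarray:
        """(x/a)^2 + (y/b)^2 - 1 in the ellipse frame; <0 inside."""
        e1, e2 = self.axes()
        d = np.asarray(pts, dtype=np.float64) - self.center
        return (d @ e1 / self.a) ** 2 + (d @ e2 / self.b) ** 2 - 1.0

    def boundary(self, n: int = 720) -> np.ndarray:
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        e1, e2 = self.axes()
        return self.center + np.outer(self.a * np.cos(t), e1) + np.outer(self.b * np.sin(t), e2)

    def support_radius(self, u: np.ndarray) -> float:
        e1, e2 = self.axes()
        return 1.0 / np.sqrt((u @ e1 / self.a) ** 2 + (u @ e2 / self.b) ** 2)

    def extent(self) -> float:
        return max(self.a, self.b)


def _x_to_ratio(x_percent: float) -> float:
    """Invert X = 200 (a-b)/(a+b) to the minor/major ratio b/a."""
    return (200.0 - x_percent) / (200.0 + x_percent)


def _tangent_offset(prev: _Ellipse, a, b, psi, u: np.ndarray) -> tuple[float, np.ndarray]:
    """Center distance along unit vector ``u`` at which a new ellipse with
    axes (a, b, psi) exactly touches ``prev``; also the contact point."""
    r0 = prev.support_radius(u) + _Ellipse((0, 0), a, b, psi).support_radius(-u)
    lo, hi = 0.6 * r0, 1.6 * r0

    def gap(d):
        e = _Ellipse(prev.center + d * u, a, b, psi)
        return float(prev.implicit(e.boundary(720)).min())

    g_lo, g_hi = gap(lo), gap(hi)
    # widen until the bracket straddles zero
    for _ in range(20):
        if g_lo < 0:
            break
        lo *= 0.8
        g_lo = gap(lo)
    for _ in range(20):
        if g_hi > 0:
            break
        hi *= 1.2
        g_hi = gap(hi)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if gap(mid) < 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-4 * r0:
            break
    d = hi  # first non-overlapping distance
    e = _Ellipse(prev.center + d * u, a, b, psi)
    bd = e.boundary(1440)
    contact = bd[int(np.argmin(prev.implicit(bd)))]
    return d, contact


def _build_cluster(rng, size, geoms, angles):
    """Chain ``size`` ellipses tangent one to the next.

    ``geoms`` is a list of (a, b, psi); ``angles`` a possibly-partial list of
    contact directions in degrees (None entries are drawn at random).
    Returns the placed ellipses and the contact records.
    """
    first = _Ellipse((0.0, 0.0), *geoms[0])
    placed = [first]
    contacts = []
    heading = None
    for k in range(1, size):
        a, b, psi = geoms[k]
        spec_angle = angles[k - 1] if angles is not None and k - 1 < len(angles) else None
        for attempt in range(80):
            if spec_angle is not None:
                ang = np.deg2rad(float(spec_angle))
            elif heading is None:
                ang = rng.uniform(0, 2 * np.pi)
            else:
                ang = heading + rng.uniform(-np.pi / 2.4, np.pi / 2.4)
            u = np.array([np.sin(ang), np.cos(ang)])  # angle measured from +col axis
            d, contact = _tangent_offset(placed[-1], a, b, psi, u)
            e = _Ellipse(placed[-1].center + d * u, a, b, psi)
            clear = all(
                other.implicit(e.boundary(360)).min() > 0.02 for other in placed[:-1]
            )
            if clear:
                placed.append(e)
                contacts.append({"point": contact, "members": (k - 1, k)})
                heading = ang
                break
            if spec_angle is not None:
                raise ValueError("objects would overlap at the requested contact angle")
        else:
            raise ValueError("could not place a tangent object without overlap")
    return placed, contacts


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a scene and return the 8-bit image plus ground truth.

    Deterministic for a fixed spec (including its seed).
    """
    rng = np.random.default_rng(spec.seed)
    n_total = int(sum(spec.clusters))
    if n_total < 1 or any(s < 1 for s in spec.clusters):
        raise ValueError("cluster sizes must be >= 1")

    if isinstance(spec.grades, str):
        grades = [spec.grades] * n_total
    else:
        grades = list(spec.grades)
        if len(grades) != n_total:
            raise ValueError("need one grade per object")

    # geometry per object
    geoms, x_true = [], []
    for g in grades:
        r = float(np.clip(rng.normal(spec.radius_px, spec.radius_spread), 10, None))
        if spec.axis_ratio is not None:
            q = 1.0 / float(spec.axis_ratio)
            x = 200.0 * (1 - q) / (1 + q)
        else:
            lo, hi = GRADE_X_RANGES[g]
            x = float(rng.uniform(lo, hi))
            q = _x_to_ratio(x)
        a = 2 * r / (1 + q)
        b = q * a
        psi = float(rng.uniform(0, np.pi))
        geoms.append((a, b, psi))
        x_true.append(x)

    # build clusters in local frames, then lay them out on the canvas
    clusters, contacts_local = [], []
    obj_idx = 0
    for ci, size in enumerate(spec.clusters):
        angles = spec.contact_angles[ci] if spec.contact_angles is not None else None
        placed, contacts = _build_cluster(rng, size, geoms[obj_idx : obj_idx + size], angles)
        clusters.append(placed)
        contacts_local.append(contacts)
        obj_idx += size

    pad = spec.margin
    cursor_r, cursor_c = pad, pad
    row_height = 0
    offsets = []
    for placed in clusters:
        pts = np.vstack([e.boundary(180) for e in placed])
        lo = pts.min(axis=0)
        hi = pts.max(axis=0)
        h, w = (hi - lo) + 1
        if cursor_c + w + pad > spec.max_row_width and cursor_c > pad:
            cursor_r += row_height + pad
            cursor_c = pad
            row_height = 0
        offsets.append(np.array([cursor_r, cursor_c]) - lo)
        cursor_c += w + pad
        row_height = max(row_height, h)
    height = int(np.ceil(cursor_r + row_height + pad))
    width = int(
        np.ceil(
            max(
                (off + np.vstack([e.boundary(180) for e in cl]).max(axis=0))[1]
                for off, cl in zip(offsets, clusters)
            )
            + pad
        )
    )

    objects, contacts = [], []
    lab = 0
    for ci in range(len(clusters)):
        base = lab
        for e in clusters[ci]:
            lab += 1
            objects.append(
                (_Ellipse(e.center + offsets[ci], e.a, e.b, e.psi), lab, ci + 1)
            )
        for con in contacts_local[ci]:
            contacts.append(
                {
                    "point": tuple(con["point"] + offsets[ci]),
                    "cluster": ci + 1,
                    "labels": (base + con["members"][0] + 1, base + con["members"][1] + 1),
                }
            )

    # anti-aliased rendering via supersampling, restricted to bounding boxes
    ss = int(spec.supersample)
    cov_total = np.zeros((height, width), dtype=np.float32)
    best_cov = np.zeros((height, width), dtype=np.float32)
    labels = np.zeros((height, width), dtype=np.int32)
    for e, lb, _ in objects:
        ext = e.extent() + 3
        r0 = max(0, int(np.floor(e.center[0] - ext)))
        r1 = min(height - 1, int(np.ceil(e.center[0] + ext)))
        c0 = max(0, int(np.floor(e.center[1] - ext)))
        c1 = min(width - 1, int(np.ceil(e.center[1] + ext)))
        h, w = r1 - r0 + 1, c1 - c0 + 1
        rr = r0 + (np.arange(h * ss) + 0.5) / ss - 0.5
        cc = c0 + (np.arange(w * ss) + 0.5) / ss - 0.5
        grid = np.stack(np.meshgrid(rr, cc, indexing="ij"), axis=-1).reshape(-1, 2)
        inside = (e.implicit(grid) <= 0).reshape(h * ss, w * ss)
        cov = inside.reshape(h, ss, w, ss).mean(axis=(1, 3)).astype(np.float32)
        sl = (slice(r0, r1 + 1), slice(c0, c1 + 1))
        cov_total[sl] += cov
        better = cov > best_cov[sl]
        best_cov[sl] = np.where(better, cov, best_cov[sl])
        labels[sl] = np.where(better, lb, labels[sl])

    cov_clip = np.clip(cov_total, 0.0, 1.0)
    img = spec.background - cov_clip * (spec.background - spec.foreground)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    labels = np.where(cov_total >= 0.5, labels, 0).astype(np.int32)

    rows = []
    for (e, lb, cl), x in zip(objects, x_true):
        pix = labels == lb
        area = int(pix.sum())
        if area == 0:
            raise RuntimeError("object rendered with zero area")
        rc = np.argwhere(pix).mean(axis=0)
        rows.append(
            {
                "label": lb,
                "cluster": cl,
                "area_px": area,
                "centroid_row": float(rc[0]),
                "centroid_col": float(rc[1]),
                "a_px": e.a,
                "b_px": e.b,
                "orientation": e.psi,
                "X_true": x,
                "grade": shape_mod.grade(x),
            }
        )
    table = pd.DataFrame(rows)
    return img, GroundTruth(labels=labels, table=table, contacts=contacts)


def _grades_match(truth: GroundTruth, labels: np.ndarray, cfg: RunConfig) -> bool:
    """True when every predicted object matches a distinct true object and
    carries its grade."""
    report = shape_mod.grade_objects(
        labels, mm_per_px=cfg.mm_per_px, mean_mode=cfg.d_mean_mode,
        smooth_window=cfg.smooth_window,
    )
    tt = truth.table
    if len(report) != len(tt):
        return False
    d = cdist(
        tt[["centroid_row", "centroid_col"]].to_numpy(dtype=float),
        report[["centroid_row", "centroid_col"]].to_numpy(dtype=float),
    )
    gate = float(np.mean(np.sqrt(tt["area_px"].to_numpy(dtype=float) / np.pi)))
    assign = np.argmin(d, axis=1)
    if len(set(assign.tolist())) != len(tt) or d[np.arange(len(tt)), assign].max() > gate:
        return False
    pred = report["grade"].to_numpy()[assign]
    return bool((pred == tt["grade"].to_numpy()).all())


@dataclass
class SweepResult:
    trials: pd.DataFrame

    @property
    def coincidence_pct(self) -> float:
        if len(self.trials) == 0:
            return float("nan")
        return 100.0 * float(self.trials["coincide"].mean())

    def by_angle(self) -> pd.DataFrame:
        if len(self.trials) == 0:
            return pd.DataFrame(columns=["angle_deg", "coincidence_pct"])
        g = self.trials.groupby("angle_deg")["coincide"].mean() * 100.0
        return g.rename("coincidence_pct").reset_index()


def posture_sweep(
    angles: Sequence[float],
    reps: int,
    *,
    grade: str = "A1",
    axis_ratio: float | None = None,
    seed: int = 0,
    radius_px: float = 80.0,
    noise_sd: float = 5.0,
    n_singles: int = 2,
    config: RunConfig | None = None,
) -> SweepResult:
    """Contact-posture experiment: two tangent objects per trial, swept over
    contact angles, segmented and graded; a trial coincides when every
    object's predicted grade equals its true grade.

    ``n_singles`` isolated objects accompany the pair so that the smallest
    connected domain is a genuine single, as the area-ratio test assumes.
    """
    from .concavity import segment_scene

    cfg = config or RunConfig()
    rng = np.random.default_rng(seed)
    if not angles:
        raise ValueError("angles must be non-empty")
    records = []
    for angle in angles:
        for rep in range(int(reps)):
            spec = SceneSpec(
                clusters=(2,) + (1,) * n_singles,
                grades=grade,
                axis_ratio=axis_ratio,
                radius_px=radius_px,
                contact_angles=[[float(angle)]] + [[] for _ in range(n_singles)],
                noise_sd=noise_sd,
                seed=int(rng.integers(2**31)),
            )
            img, truth = generate_scene(spec)
            res = segment_scene(img, cfg)
            records.append(
                {
                    "angle_deg": float(angle),
                    "rep": rep,
                    "n_true": truth.n_objects,
                    "n_pred": res.n_objects,
                    "coincide": _grades_match(truth, res.labels, cfg),
                }
            )
    trials = pd.DataFrame(
        records, columns=["angle_deg", "rep", "n_true", "n_pred", "coincide"]
    )
    return SweepResult(trials=trials)


@dataclass
class StressResult:
    Y_pct: float
    mean_abs_Z_pct: float
    scenes: pd.DataFrame


def segmentation_stress(
    n_scenes: int = 200,
    *,
    seed: int = 0,
    cluster_range: tuple[int, int] = (2, 5),
    n_singles: int = 2,
    radius_px: float = 80.0,
    noise_sd: float = 5.0,
    config: RunConfig | None = None,
) -> StressResult:
    """Seeded stress suite: scenes with one random tangent cluster (size
    drawn from ``cluster_range``) plus isolated objects, segmented and scored
    against ground truth.  Pools C and L over scenes for Y and averages |Z|
    over correctly segmented objects.
    """
    from .concavity import segment_scene
    from .metrics import evaluate_segmentation

    cfg = config or RunConfig()
    rng = np.random.default_rng(seed)
    grade_pool = np.array(["A1", "A2", "A3", "B"])
    tot_c = tot_l = 0
    abs_z: list[float] = []
    rows = []
    for si in range(int(n_scenes)):
        m = int(rng.integers(cluster_range[0], cluster_range[1] + 1))
        n_obj = m + n_singles
        spec = SceneSpec(
            clusters=(m,) + (1,) * n_singles,
            grades=list(rng.choice(grade_pool, size=n_obj)),
            radius_px=radius_px,
            noise_sd=noise_sd,
            seed=int(rng.integers(2**31)),
        )
        img, truth = generate_scene(spec)
        res = segment_scene(img, cfg)
        ev = evaluate_segmentation(truth, res.labels, pre_split_mask=res.mask)
        tot_c += ev.C
        tot_l += ev.L
        if len(ev.matches):
            abs_z.extend(ev.matches.loc[ev.matches["correct"], "Z_percent"].abs().tolist())
        rows.append(
            {"scene": si, "cluster_size": m, "L": ev.L, "C": ev.C, "Y": ev.Y,
             "mean_abs_Z": ev.mean_abs_Z}
        )
    scenes = pd.DataFrame(rows)
    return StressResult(
        Y_pct=100.0 * tot_c / tot_l,
        mean_abs_Z_pct=float(np.mean(abs_z)) if abs_z else float("nan"),
        scenes=scenes,
    )
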
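"""Evaluation statistics: segmentation accuracy Y, area loss rate Z, and
macro-averaged precision/recall/F1 over a grade confusion matrix.

Conventions
-----------
* Y = C / L: correctly segmented objects over the true object count.
* Z = (1 - K1/K2) * 100 with K1 = S1/Sa (an object's area share among its
  cluster's reference areas) and K2 = S2/Sb (its share after splitting,
  within the contact-state region area).  Z may be negative when a split
  over-credits an object; it is recorded as-is.
* macro-F1 is the harmonic mean of macro-P and macro-R (the means of the
  per-class precisions and recalls) — note this differs from averaging
  per-class F1 values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "SegEval",
    "GradeEval",
    "segmentation_accuracy",
    "area_loss",
    "macro_f1",
    "confusion_counts",
    "evaluate_segmentation",
]


def segmentation_accuracy(c: int, l: int) -> float:
    """Y = C / L."""
    if l <= 0:
        raise ValueError("true object count must be positive")
    if not 0 <= c <= l:
        raise ValueError("need 0 <= C <= L")
    return c / l


def area_loss(s_ref: float, s_ref_total: float, s_split: float, s_split_total: float) -> float:
    """Loss rate Z = (1 - K1/K2) * 100 in percent.

    K1 = s_ref / s_ref_total is the object's area share in the non-contact
    reference; K2 = s_split / s_split_total its share after segmentation of
    the contact-state region.
    """
    if min(s_ref, s_ref_total, s_split, s_split_total) <= 0:
        raise ValueError("areas must be positive")
    k1 = s_ref / s_ref_total
    k2 = s_split / s_split_total
    return (1.0 - k1 / k2) * 100.0


@dataclass
class GradeEval:
    per_class: pd.DataFrame  # TP, FP, FN, P, R per class
    macro_P: float
    macro_R: float
    macro_F1: float

    @property
    def m(self) -> int:
        return len(self.per_class)


def macro_f1(confusions) -> GradeEval:
    """Macro-averaged precision/recall/F1 from per-class counts.

    ``confusions`` maps class label to (TP, FP, FN) or is a DataFrame with
    TP/FP/FN columns.  Classes with an empty denominator score 0 for the
    affected rate (penalizing empty predictions rather than skipping them).
    """
    if isinstance(confusions, pd.DataFrame):
        df = confusions.copy()
    else:
        if not confusions:
            raise ValueError("empty confusion table")
        df = pd.DataFrame.from_dict(confusions, orient="index", columns=["TP", "FP", "FN"])
    if len(df) == 0:
        raise ValueError("empty confusion table")
    tp = df["TP"].to_numpy(dtype=float)
    fp = df["FP"].to_numpy(dtype=float)
    fn = df["FN"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        r = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
    df["P"] = p
    df["R"] = r
    macro_p = float(p.mean())
    macro_r = float(r.mean())
    denom = macro_p + macro_r
    macro = 0.0 if denom == 0 else 2.0 * macro_p * macro_r / denom
    return GradeEval(per_class=df, macro_P=macro_p, macro_R=macro_r, macro_F1=macro)


def confusion_counts(y_true, y_pred, classes=None) -> pd.DataFrame:
    """Per-class TP/FP/FN counts for a multi-class label comparison."""
    y_true = pd.Series(list(y_true))
    y_pred = pd.Series(list(y_pred))
    if len(y_true) != len(y_pred):
        raise ValueError("label lists differ in length")
    if classes is None:
        classes = sorted(set(y_true) | set(y_pred))
    rows = {}
    for c in classes:
        tp = int(((y_true == c) & (y_pred == c)).sum())
        fp = int(((y_true != c) & (y_pred == c)).sum())
        fn = int(((y_true == c) & (y_pred != c)).sum())
        rows[c] = (tp, fp, fn)
    return pd.DataFrame.from_dict(rows, orient="index", columns=["TP", "FP", "FN"])


@dataclass
class SegEval:
    """Instance-level segmentation evaluation against ground truth."""

    L: int
    C: int
    Y: float
    matches: pd.DataFrame = field(repr=False, default=None)
    mean_abs_Z: float = float("nan")


def _greedy_match(true_xy: np.ndarray, pred_xy: np.ndarray, gate: float):
    """Greedy mutual nearest matching under a distance gate."""
    if len(true_xy) == 0 or len(pred_xy) == 0:
        return []
    d = cdist(true_xy, pred_xy)
    pairs = []
    used_t, used_p = set(), set()
    order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
    for ti, pi in order:
        if d[ti, pi] > gate:
            break
        if ti in used_t or pi in used_p:
            continue
        pairs.append((int(ti), int(pi), float(d[ti, pi])))
        used_t.add(ti)
        used_p.add(pi)
    return pairs


def evaluate_segmentation(
    truth,
    pred_labels: np.ndarray,
    pre_split_mask: np.ndarray | None = None,
    *,
    z_limit: float = 10.0,
    overlap_limit: float = 0.5,
) -> SegEval:
    """Score a predicted label map against generator ground truth.

    ``truth`` provides ``labels`` (instance map) and ``table`` (per-object
    label, cluster, area_px, centroid_row, centroid_col).  Predicted objects
    are matched to true objects greedily by centroid distance, gated at one
    mean true radius.  A match counts as correctly segmented when its area
    loss satisfies |Z| <= ``z_limit`` percent and its mask overlaps the true
    instance by more than ``overlap_limit``; unmatched predictions are
    subtracted from the correct count.  ``pre_split_mask`` (the binary mask
    before any cut) supplies the contact-state areas Sb; without it the
    summed matched prediction areas per cluster stand in.
    """
    from skimage import measure as _measure

    tt = truth.table
    tlabels = np.asarray(truth.labels)
    plabels = np.asarray(pred_labels)
    L = len(tt)
    if L == 0:
        raise ValueError("ground truth holds no objects")

    pred_props = {p.label: p for p in _measure.regionprops(plabels)}
    pred_ids = sorted(pred_props)
    pred_xy = np.array([pred_props[i].centroid for i in pred_ids], dtype=float).reshape(-1, 2)
    true_xy = tt[["centroid_row", "centroid_col"]].to_numpy(dtype=float)
    gate = float(np.mean(np.sqrt(tt["area_px"].to_numpy(dtype=float) / np.pi)))
    pairs = _greedy_match(true_xy, pred_xy, gate)

    # contact-state region areas Sb, per true cluster
    if pre_split_mask is not None:
        comp = _measure.label(np.asarray(pre_split_mask, bool), connectivity=2)
    else:
        comp = None
    sa_by_cluster = tt.groupby("cluster")["area_px"].sum().to_dict()

    sb_by_cluster: dict = {}
    for row in tt.itertuples():
        cl = row.cluster
        if cl in sb_by_cluster:
            continue
        if comp is not None:
            r, c = int(round(row.centroid_row)), int(round(row.centroid_col))
            cid = comp[np.clip(r, 0, comp.shape[0] - 1), np.clip(c, 0, comp.shape[1] - 1)]
            if cid > 0:
                sb_by_cluster[cl] = int((comp == cid).sum())
    # fallback: summed matched prediction areas
    matched_pred_area_by_cluster: dict = {}
    for ti, pi, _ in pairs:
        cl = tt.iloc[ti]["cluster"]
        matched_pred_area_by_cluster[cl] = (
            matched_pred_area_by_cluster.get(cl, 0) + int(pred_props[pred_ids[pi]].area)
        )
    rows = []
    for ti, pi, dist in pairs:
        trow = tt.iloc[ti]
        plab = pred_ids[pi]
        s1 = float(trow["area_px"])
        sa = float(sa_by_cluster[trow["cluster"]])
        s2 = float(pred_props[plab].area)
        sb = float(
            sb_by_cluster.get(trow["cluster"], matched_pred_area_by_cluster[trow["cluster"]])
        )
        z = area_loss(s1, sa, s2, sb)
        inter = int(((tlabels == trow["label"]) & (plabels == plab)).sum())
        overlap = inter / s1
        correct = abs(z) <= z_limit and overlap > overlap_limit
        rows.append(
            {
                "true_label": int(trow["label"]),
                "pred_label": int(plab),
                "dist_px": dist,
                "overlap": overlap,
                "Z_percent": z,
                "correct": correct,
            }
        )
    matches = pd.DataFrame(
        rows, columns=["true_label", "pred_label", "dist_px", "overlap", "Z_percent", "correct"]
    )
    n_correct = int(matches["correct"].sum()) if len(matches) else 0
    n_unmatched_pred = len(pred_ids) - len(pairs)
    C = max(0, min(L, n_correct - n_unmatched_pred))
    y = segmentation_accuracy(C, L)
    if len(matches) and matches["correct"].any():
        mean_abs_z = float(matches.loc[matches["correct"], "Z_percent"].abs().mean())
    else:
        mean_abs_z = float("nan")
    return SegEval(L=L, C=C, Y=y, matches=matches, mean_abs_Z=mean_abs_z)
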
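"""Free-response ROC evaluation of case-level detections.

A detection is a true positive iff its footprint shares at least one voxel
with an aneurysm mask ("contains a part of the aneurysm"); an aneurysm is
detected iff at least one true-positive detection touches it, and counts
once for sensitivity no matter how many detections hit it.  Sensitivity is
pooled: detected aneurysms over total aneurysms across all cases; the
false-positive burden is total FPs over the number of cases.  Sweeping the
detection score threshold traces the FROC curve, from which the standard
operating points — FPs/case at a fixed sensitivity, sensitivity at a fixed
FPs/case, and the curve's top point — are read with linear interpolation
between adjacent curve points.

Size/location breakdowns use the reporting bins
``< 3.0, 3.0-5.9, 6.0-8.9, >= 9.0`` mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volume import AnnotationSet

__all__ = [
    "FROCCurve",
    "match_detections",
    "froc_curve",
    "operating_points",
    "stratified_report",
    "plot_froc",
    "DEFAULT_SIZE_BINS_MM",
]

DEFAULT_SIZE_BINS_MM = (3.0, 6.0, 9.0)  # edges of <3, 3-5.9, 6-8.9, >=9


@dataclass
class FROCCurve:
    """Ordered operating points (one per swept threshold).

    ``points`` is a list of ``(threshold, fps_per_case, sensitivity)``
    sorted by descending threshold, so FPs/case and sensitivity are both
    non-decreasing along the list.
    """

    points: list[tuple[float, float, float]]
    n_cases: int
    n_aneurysms: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["threshold", "fps_per_case", "sensitivity"])

    @property
    def max_sensitivity(self) -> float:
        return max((p[2] for p in self.points), default=0.0)


def match_detections(detections, annotations: AnnotationSet):
    """Label detections TP/FP against one case's ground truth.

    Mutates each detection's ``is_true_positive`` and
    ``matched_annotation_ids``; returns ``(detections, detected_flags)``
    where ``detected_flags`` maps annotation id -> bool.
    """
    detected = {ann.id: False for ann in annotations}
    for det in detections:
        hits = []
        for ann in annotations:
            if det.footprint.shape != ann.mask.shape:
                raise ValueError("detection and annotation grids do not match")
            if (det.footprint & ann.mask).any():
                hits.append(ann.id)
                detected[ann.id] = True
        det.matched_annotation_ids = tuple(hits)
        det.is_true_positive = bool(hits)
    return detections, detected


def froc_curve(cases, thresholds=None) -> FROCCurve:
    """FROC over a cohort.

    ``cases`` is a list of ``(detections, annotations)`` pairs.  For each
    threshold t (by default the descending unique detection scores),
    detections with score >= t are kept and re-matched; sensitivity is
    pooled over aneurysms, FPs are averaged over cases.
    """
    cases = list(cases)
    if not cases:
        raise ValueError("froc_curve needs at least one case")
    n_aneurysms = sum(len(anns) for _, anns in cases)
    if n_aneurysms == 0:
        raise ValueError("cohort contains no aneurysms; sensitivity is undefined")
    n_cases = len(cases)

    # matching is threshold-independent: label every detection once
    per_det = []  # (case_idx, score, is_tp, matched ids)
    for ci, (dets, anns) in enumerate(cases):
        match_detections(dets, anns)
        for d in dets:
            per_det.append((ci, float(d.score), d.is_true_positive, d.matched_annotation_ids))

    if thresholds is None:
        thresholds = sorted({s for _, s, _, _ in per_det}, reverse=True)
    thresholds = list(thresholds)
    if not thresholds:
        thresholds = [1.0]

    points = []
    for t in sorted(thresholds, reverse=True):
        fps = 0
        hit: set[tuple[int, int]] = set()
        for ci, s, is_tp, ids in per_det:
            if s >= t:
                if is_tp:
                    hit.update((ci, a) for a in ids)
                else:
                    fps += 1
        points.append((float(t), fps / n_cases, len(hit) / n_aneurysms))
    return FROCCurve(points, n_cases, n_aneurysms)


def _interp_fps_at_sensitivity(pts, target_s):
    """Smallest FPs/case reaching sensitivity >= target along the curve,
    linearly interpolated between adjacent points."""
    pts = sorted(((f, s) for _, f, s in pts))
    best = None
    prev = None
    for f, s in pts:
        if s >= target_s:
            if prev is not None and prev[1] < target_s and s > prev[1]:
                frac = (target_s - prev[1]) / (s - prev[1])
                cand = prev[0] + frac * (f - prev[0])
            else:
                cand = f
            best = cand if best is None else min(best, cand)
        prev = (f, s)
    return best


def _interp_sensitivity_at_fps(pts, target_f):
    pts = sorted(((f, s) for _, f, s in pts))
    below = [(f, s) for f, s in pts if f <= target_f]
    if not below:
        return None
    best = max(s for _, s in below)
    above = [(f, s) for f, s in pts if f > target_f]
    if above:
        f0, s0 = max(below)
        f1, s1 = min(above)
        if f1 > f0:
            best = max(best, s0 + (target_f - f0) * (s1 - s0) / (f1 - f0))
    return best


def operating_points(curve: FROCCurve, sensitivity_target: float = 0.80,
                     fps_target: float = 3.0) -> dict:
    """Headline operating points of a FROC curve.

    Returns the curve's top point (max sensitivity with its FPs/case), the
    FPs/case needed to reach ``sensitivity_target`` (None when the target
    is unreachable) and the sensitivity available at ``fps_target``
    FPs/case, with linear interpolation between adjacent curve points.
    """
    if not curve.points:
        raise ValueError("empty FROC curve")
    top = max(curve.points, key=lambda p: (p[2], -p[1]))
    fps_at_s = _interp_fps_at_sensitivity(curve.points, sensitivity_target)
    s_at_fps = _interp_sensitivity_at_fps(curve.points, fps_target)
    return {
        "max_sensitivity": top[2],
        "fps_at_max_sensitivity": top[1],
        "fps_at_sensitivity": fps_at_s,
        "sensitivity_target": sensitivity_target,
        "sensitivity_target_reachable": fps_at_s is not None,
        "sensitivity_at_fps": s_at_fps,
        "fps_target": fps_target,
    }


def plot_froc(curves: dict[str, FROCCurve], path) -> None:
    """Write a sensitivity vs FPs/case plot for one or more curves."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for name, curve in curves.items():
        pts = sorted((f, s) for _, f, s in curve.points)
        ax.plot([f for f, _ in pts], [s for _, s in pts], marker="o", label=name)
    ax.axhline(0.8, color="gray", linestyle="--", linewidth=0.8)
    ax.set_xlabel("FPs / case")
    ax.set_ylabel("Sensitivity")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _size_bin(d_mm, edges=DEFAULT_SIZE_BINS_MM) -> str:
    labels = [f"<{edges[0]:.1f}"] + [
        f"{lo:.1f}-{hi - 0.1:.1f}" for lo, hi in zip(edges[:-1], edges[1:])
    ] + [f">={edges[-1]:.1f}"]
    for i, e in enumerate(edges):
        if d_mm < e:
            return labels[i]
    return labels[-1]


def stratified_report(cases, size_bin_edges=DEFAULT_SIZE_BINS_MM) -> dict[str, pd.DataFrame]:
    """Per-size-bin and per-location sensitivity tables.

    ``cases`` is a list of ``(detections, annotations)`` pairs; detections
    are matched at their current scores.  Empty bins appear with n = 0 and
    NaN sensitivity; if no annotation carries a location label the
    location table is empty while the size table is still produced.
    """
    rows = []
    for dets, anns in cases:
        _, flags = match_detections(dets, anns)
        for ann in anns:
            rows.append(
                {
                    "diameter_mm": ann.equivalent_diameter_mm,
                    "size_bin": _size_bin(ann.equivalent_diameter_mm, size_bin_edges),
                    "location": ann.location_label,
                    "detected": bool(flags[ann.id]),
                }
            )
    df = pd.DataFrame(rows, columns=["diameter_mm", "size_bin", "location", "detected"])

    edges = size_bin_edges
    all_bins = [f"<{edges[0]:.1f}"] + [
        f"{lo:.1f}-{hi - 0.1:.1f}" for lo, hi in zip(edges[:-1], edges[1:])
    ] + [f">={edges[-1]:.1f}"]

    def _table(group_col, order=None):
        if df.empty:
            g = pd.DataFrame(columns=["n", "detected", "missed", "sensitivity"])
        else:
            g = df.groupby(group_col)["detected"].agg(n="size", detected="sum")
            g["missed"] = g["n"] - g["detected"]
            g["sensitivity"] = g["detected"] / g["n"]
        if order is not None:
            g = g.reindex(order)
            g["n"] = g["n"].fillna(0).astype(int)
            g["sensitivity"] = g["detected"] / g["n"].where(g["n"] > 0)
        return g

    size_table = _table("size_bin", order=all_bins)
    has_locations = (not df.empty) and bool((df["location"] != "").any())
    loc_table = _table("location") if has_locations else \
        pd.DataFrame(columns=["n", "detected", "missed", "sensitivity"])
    return {"by_size": size_table, "by_location": loc_table}
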
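"""From per-candidate probabilities to case-level detections.

Three rules turn classifier outputs into detections:

1. *Thresholding* — a candidate is positive iff its probability is
   strictly greater than tau (default 0.5).
2. *Voting* — the union of positive candidates' footprints (patch bounds
   intersected with the artery mask) is split into 26-connected
   components; a component is emitted as a detection region only when at
   least ``min_votes`` (default 6, i.e. "more than five") positive
   candidates' footprints touch it.  The region score is the maximum
   member probability.
3. *Separation* — regions whose representative points are closer than
   ``min_separation_vox`` voxels (default 16, about 6.25 mm at 0.3906 mm
   spacing) are merged into a single detection keeping the higher score;
   farther regions stay distinct.

All three are deterministic and independent of candidate input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "DetectionRegion",
    "positive_candidates",
    "vote_regions",
    "separate_detections",
    "detect_case",
]

CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=int)


@dataclass
class DetectionRegion:
    """One aggregated positive region in a volume."""

    footprint: np.ndarray  # boolean mask
    representative_point: tuple[int, int, int]
    vote_count: int
    score: float
    matched_annotation_ids: tuple[int, ...] = ()
    is_true_positive: bool | None = None
    case_id: str = ""

    def to_record(self) -> dict:
        return {
            "case_id": self.case_id,
            "representative_point_ijk": [int(c) for c in self.representative_point],
            "score": float(self.score),
            "vote_count": int(self.vote_count),
            "is_true_positive": self.is_true_positive,
        }


def positive_candidates(candidates, tau: float = 0.5) -> list:
    """Candidates with probability strictly greater than ``tau``."""
    out = []
    for c in candidates:
        p = c.probability
        if p is None:
            raise ValueError("candidate has no probability; run the classifier first")
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"probability {p} outside [0, 1]")
        if p > tau:
            out.append(c)
    return out


def _footprint_mask(candidate, artery_mask) -> np.ndarray:
    m = np.zeros(artery_mask.shape, dtype=bool)
    sl = candidate.footprint_slices(artery_mask.shape)
    m[sl] = artery_mask[sl]
    return m


def vote_regions(candidates, artery_mask: np.ndarray, min_votes: int = 6,
                 case_id: str = "") -> list[DetectionRegion]:
    """Connected-component voting over positive candidates' footprints.

    Components of the footprint union (26-connectivity, inside the artery
    mask) are kept when at least ``min_votes`` candidates' footprints
    intersect them; the representative point is the component centroid
    rounded to the nearest voxel.
    """
    if not candidates:
        return []
    union = np.zeros(artery_mask.shape, dtype=bool)
    foot = []
    for c in candidates:
        m = _footprint_mask(c, artery_mask)
        foot.append(m)
        union |= m
    labels, n = ndimage.label(union, structure=CONNECTIVITY_26)
    regions = []
    for lab in range(1, n + 1):
        comp = labels == lab
        members = [i for i, m in enumerate(foot) if (m & comp).any()]
        if len(members) < min_votes:
            continue
        score = max(float(candidates[i].probability) for i in members)
        centroid = np.argwhere(comp).mean(axis=0)
        regions.append(
            DetectionRegion(
                footprint=comp,
                representative_point=tuple(int(round(x)) for x in centroid),
                vote_count=len(members),
                score=score,
                case_id=case_id,
            )
        )
    regions.sort(key=lambda r: (-r.score, r.representative_point))
    return regions


def separate_detections(regions, min_separation_vox: float = 16.0) -> list[DetectionRegion]:
    """Merge regions closer than the separation threshold.

    Regions are scanned in descending score order (ties broken by
    representative point, so the result does not depend on input order);
    a region within ``min_separation_vox`` (Euclidean, voxels) of an
    already kept detection is absorbed into it — footprints union, votes
    add, the higher score and its representative point win.
    """
    ordered = sorted(regions, key=lambda r: (-r.score, r.representative_point))
    kept: list[DetectionRegion] = []
    for reg in ordered:
        merged = False
        for det in kept:
            d = np.linalg.norm(
                np.asarray(det.representative_point, float)
                - np.asarray(reg.representative_point, float)
            )
            if d < min_separation_vox:
                det.footprint = det.footprint | reg.footprint
                det.vote_count += reg.vote_count
                det.score = max(det.score, reg.score)
                merged = True
                break
        if not merged:
            kept.append(
                DetectionRegion(
                    footprint=reg.footprint.copy(),
                    representative_point=reg.representative_point,
                    vote_count=reg.vote_count,
                    score=reg.score,
                    case_id=reg.case_id,
                )
            )
    return kept


def detect_case(
    candidates,
    artery_mask: np.ndarray,
    tau: float = 0.5,
    min_votes: int = 6,
    min_separation_vox: float = 16.0,
    case_id: str = "",
) -> list[DetectionRegion]:
    """Full aggregation for one case: threshold, vote, separate."""
    pos = positive_candidates(candidates, tau)
    regions = vote_regions(pos, artery_mask, min_votes, case_id)
    return separate_detections(regions, min_separation_vox)
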
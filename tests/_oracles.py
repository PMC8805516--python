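"""Independent brute-force reference implementations used only by tests.

Everything here is pure Python over voxel sets — no scipy labeling, no
vectorized shortcuts shared with the library code paths they check.
"""

from __future__ import annotations

from collections import deque


def footprint_voxels(candidate, artery_mask) -> frozenset:
    """Patch bounds clipped to the volume, intersected with the artery mask."""
    shape = artery_mask.shape
    vox = []
    (lo0, hi0), (lo1, hi1), (lo2, hi2) = candidate.bounds()
    for i in range(max(lo0, 0), min(hi0, shape[0])):
        for j in range(max(lo1, 0), min(hi1, shape[1])):
            for k in range(max(lo2, 0), min(hi2, shape[2])):
                if artery_mask[i, j, k]:
                    vox.append((i, j, k))
    return frozenset(vox)


def flood_fill_components(voxels: set) -> list[set]:
    """26-connected components of a voxel set via breadth-first search."""
    remaining = set(voxels)
    comps = []
    while remaining:
        seed = remaining.pop()
        comp = {seed}
        queue = deque([seed])
        while queue:
            i, j, k = queue.popleft()
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    for dk in (-1, 0, 1):
                        if di == dj == dk == 0:
                            continue
                        nb = (i + di, j + dj, k + dk)
                        if nb in remaining:
                            remaining.remove(nb)
                            comp.add(nb)
                            queue.append(nb)
        comps.append(comp)
    return comps


def brute_force_vote_regions(candidates, artery_mask, min_votes):
    """Reference for aggregate.vote_regions: explicit union + flood fill +
    per-candidate intersection counts.  Returns a set of
    (frozenset(component), vote_count, score) triples."""
    foot = [footprint_voxels(c, artery_mask) for c in candidates]
    union = set()
    for f in foot:
        union |= f
    out = set()
    for comp in flood_fill_components(union):
        members = [i for i, f in enumerate(foot) if f & comp]
        if len(members) >= min_votes:
            score = max(candidates[i].probability for i in members)
            out.add((frozenset(comp), len(members), round(score, 9)))
    return out


def brute_force_separate(regions, min_separation):
    """Reference for aggregate.separate_detections: pairwise distance scan
    over regions in descending-score order.  Returns a list of
    (frozenset(footprint), score) in the order kept."""
    def rep(r):
        return r.representative_point

    ordered = sorted(regions, key=lambda r: (-r.score, rep(r)))
    kept = []  # (footprint set, rep point, score)
    for r in ordered:
        foot = {tuple(v) for v in zip(*[list(a) for a in r.footprint.nonzero()])}
        target = None
        for entry in kept:
            d2 = sum((a - b) ** 2 for a, b in zip(entry[1], rep(r)))
            if d2 < min_separation**2:
                target = entry
                break
        if target is None:
            kept.append([foot, rep(r), r.score])
        else:
            target[0] |= foot
            target[2] = max(target[2], r.score)
    return [(frozenset(f), round(s, 9)) for f, _, s in kept]


def brute_force_froc(cases, thresholds=None):
    """Reference for froc.froc_curve: exhaustive threshold loop with voxel-set
    matching.  ``cases`` is a list of (detections, annotations)."""
    ann_vox = []
    det_info = []  # (case_idx, score, footprint voxel set)
    n_aneurysms = 0
    for ci, (dets, anns) in enumerate(cases):
        case_anns = {}
        for ann in anns:
            case_anns[ann.id] = {tuple(v) for v in zip(*[list(a) for a in ann.mask.nonzero()])}
            n_aneurysms += 1
        ann_vox.append(case_anns)
        for d in dets:
            foot = {tuple(v) for v in zip(*[list(a) for a in d.footprint.nonzero()])}
            det_info.append((ci, float(d.score), foot))

    if thresholds is None:
        thresholds = sorted({s for _, s, _ in det_info}, reverse=True) or [1.0]

    points = []
    for t in sorted(thresholds, reverse=True):
        fps = 0
        hit = set()
        for ci, s, foot in det_info:
            if s < t:
                continue
            matched = [aid for aid, vox in ann_vox[ci].items() if foot & vox]
            if matched:
                hit.update((ci, aid) for aid in matched)
            else:
                fps += 1
        points.append((float(t), fps / len(cases), len(hit) / n_aneurysms))
    return points
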
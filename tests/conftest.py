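import numpy as np
import pytest

from aneuscan.enhance import (
    CandidateParams,
    candidate_features,
    crop_and_label,
    extract_candidate_points,
    shape_filter,
)
from aneuscan.phantom import PhantomConfig, generate_phantom
from aneuscan.preprocess import extract_arteries, nyul_apply, nyul_train


STUDY_PHANTOM = dict(
    volume_shape=(64, 64, 64),
    n_vessels=3,
    vessel_radius_range_mm=(0.6, 1.2),
    n_aneurysms=2,
    aneurysm_diameter_range_mm=(3.0, 6.0),
)


@pytest.fixture(scope="session")
def phantom_case():
    """One seeded 64^3 phantom: (volume, vessel_mask, annotations)."""
    return generate_phantom(PhantomConfig(seed=7, **STUDY_PHANTOM))


@pytest.fixture(scope="session")
def processed_case(phantom_case):
    """The phantom pushed through normalization, artery extraction, shape
    filtering and candidate labeling/featurization."""
    from scipy import ndimage

    vol, vessel_mask, anns = phantom_case
    norm = nyul_apply(vol, nyul_train([vol]))
    art = extract_arteries(norm)
    resp = shape_filter(
        norm, (0.8, 1.2, 1.8, 2.7),
        mask=ndimage.binary_dilation(art.artery_mask, iterations=2),
    )
    pts = extract_candidate_points(
        resp, art.artery_mask,
        CandidateParams(min_response_percentile=30.0, nms_radius_mm=0.8,
                        max_candidates=60),
    )
    cands = crop_and_label(norm, pts, anns, 24)
    for i, c in enumerate(cands):
        candidate_features(c, resp, art.artery_mask)
        c.case_id = "case_000"
    return {
        "volume": norm,
        "vessel_mask": vessel_mask,
        "annotations": anns,
        "artery": art,
        "response": resp,
        "candidates": cands,
    }


def make_labeled_candidates(n_cases=8, per_case=8, side=12, seed=0):
    """Synthetic labeled candidates for classifier tests: positives carry a
    bright central blob, negatives a bright off-axis tube."""
    from aneuscan.enhance import Candidate

    rng = np.random.default_rng(seed)
    grid = np.indices((side,) * 3) - side // 2
    blob = np.exp(-(grid**2).sum(0) / (2 * (side / 8) ** 2))
    tube = np.exp(-((grid[1] ** 2 + grid[2] ** 2)) / (2 * (side / 10) ** 2))
    out = []
    for ci in range(n_cases):
        for j in range(per_case):
            positive = j % 2 == 0
            patch = rng.normal(20, 5, size=(side,) * 3)
            patch += 80 * (blob if positive else tube)
            out.append(
                Candidate(
                    center_ijk=(side // 2,) * 3,
                    patch=patch.astype(np.float32),
                    peak_scale_mm=1.0,
                    label="positive" if positive else "negative",
                    case_id=f"case_{ci:03d}",
                )
            )
    return out
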
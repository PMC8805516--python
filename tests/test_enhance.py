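import numpy as np
import pytest

from aneuscan.enhance import (
    Candidate,
    CandidateParams,
    CandidatePrefilter,
    candidate_features,
    crop_and_label,
    crop_patch,
    extract_candidate_points,
    prefilter_candidates,
    shape_filter,
    _component_shape,
)
from aneuscan.volume import Annotation, AnnotationSet, Volume, equivalent_diameter_mm

BLOB_MAX_CONST = (2.0 / 3.0) * (3.0 / 5.0) ** 2.5  # peak of s^2 s0^3/(s0^2+s^2)^(5/2)


def gaussian_blob_volume(amplitude, sigma_vox, n=33):
    g = np.indices((n, n, n)) - n // 2
    return Volume(amplitude * np.exp(-(g**2).sum(0) / (2 * sigma_vox**2)), 1.0)


class TestShapeFilter:
    def test_blob_response_matches_closed_form(self):
        A, s0 = 50.0, 2.0
        vol = gaussian_blob_volume(A, s0)
        resp = shape_filter(vol, (1.0, s0 * np.sqrt(2 / 3), 2.0, 2.5))
        c = (16, 16, 16)
        expected = A * BLOB_MAX_CONST
        assert resp.blob[c] == pytest.approx(expected, rel=0.05)
        assert resp.blob[c] > resp.line[c]
        assert resp.blob[c] > resp.plane[c]

    def test_cylinder_suppressed_by_blob_filter(self):
        A, s0, m = 50.0, 2.0, 49
        gy, gz = np.meshgrid(np.arange(m) - m // 2, np.arange(m) - m // 2,
                             indexing="ij")
        tube = A * np.exp(-(gy**2 + gz**2) / (2 * s0**2))
        vol = Volume(np.broadcast_to(tube, (m, m, m)).copy(), 1.0)
        resp = shape_filter(vol, (1.0, 1.6, 2.0))
        c = (m // 2,) * 3
        assert resp.line[c] > 0
        assert resp.blob[c] < 0.05 * resp.line[c]

    def test_constant_volume_all_zero(self):
        resp = shape_filter(Volume(np.full((20, 20, 20), 9.0), 1.0), (1.0, 2.0))
        assert not resp.blob.any() and not resp.line.any() and not resp.plane.any()

    def test_responses_nonnegative(self, processed_case):
        resp = processed_case["response"]
        assert resp.blob.min() >= 0 and resp.line.min() >= 0 and resp.plane.min() >= 0

    def test_anisotropic_volume_rejected(self):
        vol = Volume(np.zeros((10, 10, 10)), (1.0, 1.0, 2.0))
        with pytest.raises(ValueError, match="isotropic"):
            shape_filter(vol, (1.0,))

    def test_masked_equals_unmasked_inside_mask(self):
        vol = gaussian_blob_volume(30.0, 2.0, n=25)
        mask = np.zeros(vol.shape, dtype=bool)
        mask[8:17, 8:17, 8:17] = True
        full = shape_filter(vol, (1.5, 2.0))
        part = shape_filter(vol, (1.5, 2.0), mask=mask)
        np.testing.assert_allclose(part.blob[mask], full.blob[mask], rtol=1e-5)
        assert not part.blob[~mask].any()

    @pytest.mark.parametrize("s0", [1.5, 2.5])
    def test_scale_selection_within_one_step(self, s0):
        scales = (0.8, 1.2, 1.8, 2.7, 4.0)
        vol = gaussian_blob_volume(40.0, s0, n=41)
        resp = shape_filter(vol, scales)
        best = resp.best_scale_mm[(20, 20, 20)]
        optimal = s0 * np.sqrt(2 / 3)
        idx_opt = int(np.argmin(np.abs(np.array(scales) - optimal)))
        idx_best = scales.index(best)
        assert abs(idx_best - idx_opt) <= 1

    def test_rotation_equivariance_for_axis_rotations(self):
        # an off-center blob rotated by 90 degrees: responses map with the grid
        n = 29
        g = np.indices((n, n, n)) - n // 2
        off = np.array([4, -3, 2])[:, None, None, None]
        vol = Volume(60.0 * np.exp(-((g - off) ** 2).sum(0) / (2 * 2.0**2)), 1.0)
        rot = Volume(np.rot90(vol.data, k=1, axes=(0, 1)).copy(), 1.0)
        r1 = shape_filter(vol, (1.6,))
        r2 = shape_filter(rot, (1.6,))
        np.testing.assert_allclose(
            np.rot90(r1.blob, k=1, axes=(0, 1)), r2.blob, atol=1e-3
        )


class TestCandidatePoints:
    def test_zero_response_gives_empty_list(self):
        resp = shape_filter(Volume(np.zeros((16, 16, 16)), 1.0), (1.0,))
        assert extract_candidate_points(resp, np.ones((16, 16, 16), bool)) == []

    def test_single_blob_single_candidate(self):
        vol = gaussian_blob_volume(50.0, 2.0, n=25)
        resp = shape_filter(vol, (1.6,))
        mask = vol.data > 5
        pts = extract_candidate_points(
            resp, mask, CandidateParams(min_response=1.0, nms_radius_mm=3.0)
        )
        assert len(pts) == 1
        assert np.linalg.norm(np.array(pts[0][0]) - 12) <= 2

    def test_two_separated_blobs_two_candidates(self):
        n = 48
        g = np.indices((n, n, n))
        d1 = ((g - np.array([14, 14, 14])[:, None, None, None]) ** 2).sum(0)
        d2 = ((g - np.array([34, 34, 34])[:, None, None, None]) ** 2).sum(0)
        vol = Volume(50 * np.exp(-d1 / 8) + 50 * np.exp(-d2 / 8), 1.0)
        resp = shape_filter(vol, (1.6,))
        pts = extract_candidate_points(
            resp, np.ones((n, n, n), bool),
            CandidateParams(min_response=1.0, nms_radius_mm=3.0),
        )
        assert len(pts) == 2


def sphere_annotation(center, r, shape, ann_id=1, spacing=1.0):
    g = np.indices(shape)
    mask = ((g - np.asarray(center)[:, None, None, None]) ** 2).sum(0) <= r * r
    return Annotation(ann_id, mask, tuple(float(c) for c in center),
                      equivalent_diameter_mm(mask, spacing))


class TestCropAndLabel:
    def test_patch_fully_containing_aneurysm_is_positive(self):
        shape = (40, 40, 40)
        vol = Volume(np.zeros(shape), 0.3906)
        anns = AnnotationSet([sphere_annotation((20, 20, 20), 5, shape)])
        cands = crop_and_label(vol, [((20, 20, 20), 1.0)], anns, 32)
        assert cands[0].label == "positive"

    def test_patch_overlapping_half_is_partial(self):
        shape = (40, 40, 40)
        vol = Volume(np.zeros(shape), 0.3906)
        anns = AnnotationSet([sphere_annotation((20, 20, 20), 6, shape)])
        # patch spans [4, 20) on axis 0; the sphere spans [14, 26]
        cands = crop_and_label(vol, [((12, 20, 20), 1.0)], anns, 16)
        assert cands[0].label == "partial"

    def test_far_patch_is_negative(self):
        shape = (40, 40, 40)
        vol = Volume(np.zeros(shape), 0.3906)
        anns = AnnotationSet([sphere_annotation((30, 30, 30), 4, shape)])
        cands = crop_and_label(vol, [((6, 6, 6), 1.0)], anns, 8)
        assert cands[0].label == "negative"

    def test_agrees_with_brute_force_containment(self):
        rng = np.random.default_rng(3)
        shape = (36, 36, 36)
        vol = Volume(rng.normal(size=shape), 1.0)
        for _ in range(20):
            c_ann = rng.integers(6, 30, size=3)
            r = int(rng.integers(2, 6))
            ann = sphere_annotation(tuple(c_ann), r, shape)
            pt = tuple(int(v) for v in rng.integers(4, 32, size=3))
            side = int(rng.choice([8, 12, 16]))
            cand = crop_and_label(vol, [(pt, 1.0)], AnnotationSet([ann]), side)[0]
            lo = [p - side // 2 for p in pt]
            hi = [l + side for l in lo]
            vox = np.argwhere(ann.mask)
            inside = np.all((vox >= lo) & (vox < hi), axis=1)
            if inside.all():
                expected = "positive"
            elif inside.any():
                expected = "partial"
            else:
                expected = "negative"
            assert cand.label == expected

    def test_edge_patches_zero_padded(self):
        vol = Volume(np.ones((20, 20, 20)), 1.0)
        patch = crop_patch(vol.data, (0, 0, 0), 16)
        assert patch.shape == (16, 16, 16)
        assert patch[:8].sum() == 0 or patch[8:].sum() == 0  # one side is padding


class TestFeatures:
    def test_digital_sphere_sphericity(self):
        g = np.indices((17, 17, 17)) - 8
        mask = (g**2).sum(0) <= 36
        sph, _, _ = _component_shape(mask, 1.0)
        assert 0.95 <= sph < 1.0

    def test_tube_less_spherical_than_sphere(self):
        g = np.indices((17, 17, 17)) - 8
        sphere = (g**2).sum(0) <= 36
        tube = np.zeros((17, 17, 17), bool)
        tube[:, 7:10, 7:10] = True
        assert _component_shape(tube, 1.0)[0] < _component_shape(sphere, 1.0)[0]

    def test_empty_component_gets_sentinel_zeros(self, processed_case):
        resp = processed_case["response"]
        cand = Candidate(center_ijk=(12, 12, 12),
                         patch=np.zeros((24, 24, 24), np.float32),
                         peak_scale_mm=1.0)
        feats = candidate_features(cand, resp, np.zeros(resp.blob.shape, bool))
        assert feats["sphericity"] == 0.0
        assert feats["component_volume_mm3"] == 0.0
        assert feats["boundary_distance_mm"] == 0.0

    def test_feature_vector_is_complete(self, processed_case):
        from aneuscan.enhance import FEATURE_NAMES

        for cand in processed_case["candidates"]:
            assert set(cand.features) == set(FEATURE_NAMES)
            assert all(np.isfinite(v) for v in cand.features.values())


class _AcceptAll:
    """Stub estimator scoring everything 1.0."""

    def fit(self, X, y):
        return self

    def predict_proba(self, X):
        return np.column_stack([np.zeros(len(X)), np.ones(len(X))])


class TestPrefilter:
    def _labeled(self, processed_case):
        return [c for c in processed_case["candidates"]
                if c.label in ("positive", "negative")]

    def test_accept_everything_is_identity(self, processed_case):
        cands = self._labeled(processed_case)
        clf = CandidatePrefilter(estimator=_AcceptAll())
        clf.fit(cands)
        assert prefilter_candidates(cands, clf) == cands

    def test_positive_retention_at_operating_point(self, processed_case):
        cands = self._labeled(processed_case)
        clf = CandidatePrefilter(target_positive_retention=0.99)
        clf.fit(cands)
        kept = prefilter_candidates(cands, clf)
        pos = [c for c in cands if c.label == "positive"]
        kept_pos = [c for c in kept if c.label == "positive"]
        assert len(kept_pos) >= 0.99 * len(pos)

    def test_empty_input_empty_output(self, processed_case):
        clf = CandidatePrefilter(estimator=_AcceptAll())
        clf.fit(self._labeled(processed_case))
        assert prefilter_candidates([], clf) == []

    def test_untrained_classifier_rejected(self, processed_case):
        with pytest.raises(ValueError, match="untrained"):
            prefilter_candidates(self._labeled(processed_case), CandidatePrefilter())

    def test_order_preserved(self, processed_case):
        cands = self._labeled(processed_case)
        clf = CandidatePrefilter()
        clf.fit(cands)
        kept = prefilter_candidates(cands, clf)
        idx = [cands.index(c) for c in kept]
        assert idx == sorted(idx)
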
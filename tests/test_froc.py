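import numpy as np
import pytest

from aneuscan.aggregate import DetectionRegion
from aneuscan.froc import (
    FROCCurve,
    froc_curve,
    match_detections,
    operating_points,
    stratified_report,
)
from aneuscan.volume import Annotation, AnnotationSet, equivalent_diameter_mm

from _oracles import brute_force_froc

SHAPE = (32, 32, 32)


def detection(center, score, extent=2, shape=SHAPE):
    fp = np.zeros(shape, bool)
    sl = tuple(slice(max(c - extent, 0), min(c + extent + 1, s))
               for c, s in zip(center, shape))
    fp[sl] = True
    return DetectionRegion(footprint=fp, representative_point=center,
                           vote_count=6, score=score)


def annotation(center, r, ann_id=1, shape=SHAPE, spacing=1.0, location=""):
    g = np.indices(shape)
    mask = ((g - np.asarray(center)[:, None, None, None]) ** 2).sum(0) <= r * r
    return Annotation(ann_id, mask, tuple(map(float, center)),
                      equivalent_diameter_mm(mask, spacing), location)


def random_cases(rng, n_cases=5):
    cases = []
    ann_id = 0
    for _ in range(n_cases):
        anns = []
        for _ in range(int(rng.integers(1, 4))):
            ann_id += 1
            anns.append(annotation(tuple(rng.integers(6, 26, 3)),
                                   int(rng.integers(2, 5)), ann_id))
        dets = [detection(tuple(int(v) for v in rng.integers(0, 32, 3)),
                          round(float(rng.random()), 6))
                for _ in range(int(rng.integers(0, 8)))]
        cases.append((dets, AnnotationSet(anns)))
    return cases


class TestMatchDetections:
    def test_single_voxel_overlap_is_true_positive(self):
        ann = annotation((16, 16, 16), 3)
        det = detection((16, 16, 20), 0.9, extent=1)  # touches the sphere edge
        assert (det.footprint & ann.mask).sum() >= 1
        dets, flags = match_detections([det], AnnotationSet([ann]))
        assert dets[0].is_true_positive and flags[1]

    def test_clean_vessel_detection_is_false_positive(self):
        ann = annotation((8, 8, 8), 2)
        det = detection((25, 25, 25), 0.8)
        dets, flags = match_detections([det], AnnotationSet([ann]))
        assert dets[0].is_true_positive is False and not flags[1]

    def test_no_detections_zero_everything(self):
        cases = [([], AnnotationSet([annotation((10, 10, 10), 2)]))]
        curve = froc_curve(cases)
        assert all(s == 0.0 and f == 0.0 for _, f, s in curve.points)

    def test_invariant_under_annotation_relabeling(self):
        a1 = annotation((10, 10, 10), 3, ann_id=1)
        a2 = annotation((22, 22, 22), 3, ann_id=2)
        det = detection((10, 10, 10), 0.9)
        _, f_fwd = match_detections([det], AnnotationSet([a1, a2]))
        a1b = annotation((10, 10, 10), 3, ann_id=9)
        a2b = annotation((22, 22, 22), 3, ann_id=4)
        _, f_rev = match_detections([detection((10, 10, 10), 0.9)],
                                    AnnotationSet([a2b, a1b]))
        assert f_fwd[1] == f_rev[9] and f_fwd[2] == f_rev[4]


class TestFrocCurve:
    def test_oracle_detector_gives_perfect_point(self):
        anns = AnnotationSet([annotation((16, 16, 16), 3)])
        cases = [([detection((16, 16, 16), 0.99)], anns)]
        curve = froc_curve(cases)
        assert curve.points == [(0.99, 0.0, 1.0)]

    def test_all_false_positives_zero_sensitivity(self):
        anns = AnnotationSet([annotation((6, 6, 6), 2)])
        dets = [detection((25, 25, 25), 0.9), detection((25, 10, 25), 0.5)]
        curve = froc_curve([(dets, anns)])
        assert all(s == 0.0 for _, _, s in curve.points)

    def test_matches_exhaustive_threshold_loop_oracle(self):
        rng = np.random.default_rng(17)
        for trial in range(5):
            cases = random_cases(rng)
            curve = froc_curve(cases)
            expected = brute_force_froc(cases)
            assert len(curve.points) == len(expected)
            for got, exp in zip(curve.points, expected):
                assert got == pytest.approx(exp)

    def test_monotone_sensitivity_in_fps(self):
        rng = np.random.default_rng(23)
        curve = froc_curve(random_cases(rng))
        fps = [f for _, f, _ in curve.points]
        sens = [s for _, _, s in curve.points]
        assert fps == sorted(fps)   # threshold descending -> fps non-decreasing
        assert sens == sorted(sens)

    def test_no_aneurysms_rejected(self):
        with pytest.raises(ValueError, match="no aneurysms"):
            froc_curve([([], AnnotationSet([]))])


class TestOperatingPoints:
    CURVE = FROCCurve(points=[(0.9, 0.0, 0.5), (0.5, 2.0, 0.8), (0.1, 5.0, 0.9)],
                      n_cases=10, n_aneurysms=20)

    def test_fps_at_sensitivity_080(self):
        ops = operating_points(self.CURVE, sensitivity_target=0.80)
        assert ops["fps_at_sensitivity"] == pytest.approx(2.0)

    def test_sensitivity_at_3_fps_interpolated(self):
        ops = operating_points(self.CURVE, fps_target=3.0)
        assert ops["sensitivity_at_fps"] == pytest.approx(0.8 + (3 - 2) / (5 - 2) * 0.1)

    def test_perfect_curve_needs_zero_fps(self):
        curve = FROCCurve(points=[(0.5, 0.0, 1.0)], n_cases=1, n_aneurysms=1)
        assert operating_points(curve)["fps_at_sensitivity"] == pytest.approx(0.0)

    def test_unreachable_sensitivity_reported(self):
        ops = operating_points(self.CURVE, sensitivity_target=0.95)
        assert ops["fps_at_sensitivity"] is None
        assert ops["sensitivity_target_reachable"] is False

    def test_max_sensitivity_is_top_point(self):
        ops = operating_points(self.CURVE)
        assert ops["max_sensitivity"] == pytest.approx(0.9)
        assert ops["fps_at_max_sensitivity"] == pytest.approx(5.0)


class TestStratifiedReport:
    def _cases(self):
        # diameters: r=2 -> ~4.2 mm (3.0-5.9 bin); r=4 -> ~8.1 mm (6.0-8.9 bin)
        a1 = annotation((10, 10, 10), 2, 1, location="trunk")
        a2 = annotation((22, 22, 22), 4, 2, location="bifurcation")
        dets = [detection((22, 22, 22), 0.9)]  # only the large one found
        return [(dets, AnnotationSet([a1, a2]))]

    def test_fully_detected_bin_has_unit_sensitivity(self):
        report = stratified_report(self._cases())
        by_size = report["by_size"]
        assert by_size.loc["6.0-8.9", "sensitivity"] == pytest.approx(1.0)
        assert by_size.loc["3.0-5.9", "sensitivity"] == pytest.approx(0.0)

    def test_agrees_with_groupby_oracle(self):
        rng = np.random.default_rng(31)
        cases = random_cases(rng)
        report = stratified_report(cases)["by_size"]
        # direct recount
        rows = []
        for dets, anns in cases:
            _, flags = match_detections(dets, anns)
            for ann in anns:
                rows.append((ann.equivalent_diameter_mm, flags[ann.id]))
        for label, row in report.iterrows():
            if row["n"] == 0:
                continue
            if label.startswith("<"):
                sel = [d for d, _ in rows if d < 3.0]
                det = [f for d, f in rows if d < 3.0]
            elif label.startswith(">="):
                det = [f for d, f in rows if d >= 9.0]
            else:
                lo = float(label.split("-")[0])
                det = [f for d, f in rows if lo <= d < lo + 3.0]
            assert row["n"] == len(det)
            assert row["sensitivity"] == pytest.approx(np.mean(det))

    def test_pooled_sensitivity_is_bin_weighted_mean(self):
        rng = np.random.default_rng(37)
        cases = random_cases(rng)
        report = stratified_report(cases)["by_size"]
        filled = report.dropna(subset=["sensitivity"])
        pooled = (filled["sensitivity"] * filled["n"]).sum() / filled["n"].sum()
        curve = froc_curve(cases)
        # sensitivity at the loosest threshold equals the pooled breakdown
        assert curve.points[-1][2] == pytest.approx(pooled)

    def test_missing_locations_degrade_gracefully(self):
        a = annotation((10, 10, 10), 3, 1, location="")
        report = stratified_report([([], AnnotationSet([a]))])
        assert report["by_location"].empty
        assert report["by_size"]["n"].sum() == 1
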
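import numpy as np
import pytest

from aneuscan.nets import (
    NetConfig,
    build_2d,
    build_3d,
    build_md,
    constant_predictor_loss,
    cross_validate,
    predict,
    prepare_inputs,
    train,
)

from conftest import make_labeled_candidates

TINY = dict(patch_side=12, branch_depth=2, base_channels=4, se_reduction=4,
            batch_size=16, seed=3)


class TestNetConfig:
    def test_reduction_must_divide_channels(self):
        with pytest.raises(ValueError, match="se_reduction"):
            NetConfig(base_channels=6, se_reduction=4)

    @pytest.mark.parametrize("field", ["branch_depth", "base_channels", "epochs"])
    def test_positive_counts_required(self, field):
        with pytest.raises(ValueError):
            NetConfig(**{field: 0})

    def test_patch_too_small_for_depth(self):
        with pytest.raises(ValueError, match="too small"):
            NetConfig(patch_side=4, branch_depth=4)


class TestArchitectures:
    def test_forward_on_zero_input_is_finite(self):
        cfg = NetConfig(**TINY, epochs=1)
        for model, inputs in [
            (build_3d(cfg), {"patch": np.zeros((2, 1, 12, 12, 12))}),
            (build_2d(cfg), {"panel": np.zeros((2, 1, 15 * 12, 12))}),
            (build_md(cfg), {"patch": np.zeros((2, 1, 12, 12, 12)),
                             "panel": np.zeros((2, 1, 15 * 12, 12))}),
        ]:
            p = model.predict_proba(inputs)
            assert np.all(np.isfinite(p)) and np.all((p >= 0) & (p <= 1))

    def test_se_gate_outputs_in_unit_interval(self):
        from aneuscan.nets._layers import SEGate

        gate = SEGate(8, 4, np.random.default_rng(0))
        x = np.random.default_rng(1).normal(size=(3, 8, 5, 5)) + 1.0
        y = gate.forward(x)
        ratio = y / x
        assert np.all(ratio > 0) and np.all(ratio < 1)

    def test_doubling_channels_increases_parameters(self):
        small = build_3d(NetConfig(**TINY))
        big = build_3d(NetConfig(**{**TINY, "base_channels": 8}))
        assert big.num_params() > small.num_params()

    def test_md_parameter_count_is_branch_sum_plus_head(self):
        cfg = NetConfig(**TINY)
        md, m2, m3 = build_md(cfg), build_2d(cfg), build_3d(cfg)
        head = sum(p.size for p in md.head.params())
        assert md.num_params() == m2.num_branch_params() + m3.num_branch_params() + head

    def test_zeroing_one_branch_still_valid_probability(self):
        cfg = NetConfig(**TINY)
        md = build_md(cfg)
        rng = np.random.default_rng(5)
        inputs = {"patch": rng.normal(size=(2, 1, 12, 12, 12)),
                  "panel": np.zeros((2, 1, 15 * 12, 12))}
        p = md.predict_proba(inputs)
        assert np.all((p >= 0) & (p <= 1)) and np.all(np.isfinite(p))

    def test_save_load_roundtrip(self, tmp_path):
        from aneuscan.nets import ClassifierModel

        cfg = NetConfig(**TINY)
        model = build_3d(cfg)
        model.save(tmp_path / "model")
        loaded = ClassifierModel.load(tmp_path / "model")
        rng = np.random.default_rng(6)
        x = {"patch": rng.normal(size=(3, 1, 12, 12, 12))}
        np.testing.assert_array_equal(model.predict_proba(x), loaded.predict_proba(x))


class TestTraining:
    def test_memorizes_ten_candidates(self):
        cands = make_labeled_candidates(n_cases=2, per_case=5, side=12, seed=1)
        cfg = NetConfig(**TINY, epochs=120, learning_rate=3e-3)
        model, hist = train(build_3d(cfg), cands, cfg, val_candidates=cands)
        assert hist["train_loss"][-1] < 0.05

    def test_training_is_deterministic(self):
        cands = make_labeled_candidates(n_cases=4, per_case=4, side=12, seed=2)
        cfg = NetConfig(**TINY, epochs=3)
        _, h1 = train(build_md(cfg), cands, cfg)
        _, h2 = train(build_md(cfg), cands, cfg)
        assert h1["train_loss"] == h2["train_loss"]
        assert h1["val_loss"] == h2["val_loss"]

    def test_history_length_equals_epochs(self):
        cands = make_labeled_candidates(n_cases=4, per_case=4, side=12, seed=3)
        cfg = NetConfig(**TINY, epochs=4)
        _, hist = train(build_2d(cfg), cands, cfg)
        assert len(hist["train_loss"]) == len(hist["val_loss"]) == 4

    def test_single_class_rejected(self):
        cands = [c for c in make_labeled_candidates(n_cases=2, per_case=4, side=12)
                 if c.label == "positive"]
        cfg = NetConfig(**TINY, epochs=1)
        with pytest.raises(ValueError, match="positive and negative"):
            train(build_3d(cfg), cands, cfg)

    def test_beats_constant_predictor(self):
        cands = make_labeled_candidates(n_cases=8, per_case=8, side=12, seed=4)
        cfg = NetConfig(**TINY, epochs=10, learning_rate=3e-3)
        model, hist = train(build_3d(cfg), cands, cfg)
        assert hist["best_val_loss"] < constant_predictor_loss(cands, cands)

    def test_prediction_is_pure_and_repeatable(self):
        cands = make_labeled_candidates(n_cases=4, per_case=4, side=12, seed=5)
        cfg = NetConfig(**TINY, epochs=2)
        model, _ = train(build_3d(cfg), cands, cfg)
        p1 = predict(model, cands)
        p2 = predict(model, cands)
        np.testing.assert_array_equal(p1, p2)
        assert all(c.probability is not None for c in cands)


class TestCrossValidate:
    def test_single_config_grid_returns_it(self):
        cands = make_labeled_candidates(n_cases=4, per_case=4, side=12, seed=6)
        cfg = NetConfig(**TINY, epochs=1)
        best, info = cross_validate(cands, [cfg], k=4, arch="3d")
        assert best is cfg

    def test_folds_partition_cases(self):
        cands = make_labeled_candidates(n_cases=8, per_case=4, side=12, seed=7)
        cfg = NetConfig(**TINY, epochs=1)
        _, info = cross_validate(cands, [cfg], k=4, arch="3d")
        folds = info["folds"]
        assert len(folds) == 4
        assert all(len(f) == 2 for f in folds)  # 8 cases / 4 folds
        union = set().union(*folds)
        assert union == {c.case_id for c in cands}
        assert sum(len(f) for f in folds) == len(union)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cross_validate([], [], k=4)


def test_prepare_inputs_scales_and_stacks():
    cands = make_labeled_candidates(n_cases=1, per_case=4, side=12, seed=8)
    out = prepare_inputs(cands, "md", input_scale=100.0)
    assert out["patch"].shape == (4, 1, 12, 12, 12)
    assert out["panel"].shape == (4, 1, 15 * 12, 12)
    assert np.abs(out["patch"]).max() < 3.0  # intensities brought to O(1)
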
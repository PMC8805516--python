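"""End-to-end orchestration: phantom cohort -> preprocessing -> candidates ->
classifiers -> vote aggregation -> FROC, with case-level splits and seeding.

The experiment design mirrors a single-cohort internal test: cases are
split at the patient level (all candidates of a case stay on one side), the
intensity scale and the pre-filter are trained on training cases only, the
three classifier architectures are trained on the same split, and
evaluation is FROC on the held-out test cases.  All randomness flows from
one experiment seed through named sub-seeds, so a rerun reproduces every
artifact bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import aggregate as agg
from . import enhance, froc, phantom, preprocess
from .nets import (
    ClassifierModel,
    NetConfig,
    constant_predictor_loss,
    predict,
    train,
)

__all__ = [
    "ExperimentConfig",
    "split_cases",
    "run_experiment",
    "small_study_config",
    "assert_no_leakage",
]


def split_cases(case_ids, fractions, seed) -> tuple[list, list, list]:
    """Seeded case-level train/validation/test partition.

    ``fractions`` are (train, val, test) summing to 1; sizes follow
    largest-remainder rounding, so e.g. 10 cases at (0.64, 0.16, 0.2)
    give (6, 2, 2).  The three lists are disjoint and exhaustive.
    """
    case_ids = list(case_ids)
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f < 0 for f in fractions) or abs(sum(fractions) - 1) > 1e-9:
        raise ValueError("fractions must be three non-negatives summing to 1")
    n = len(case_ids)
    n_parts = sum(1 for f in fractions if f > 0)
    if n < n_parts:
        raise ValueError(f"cannot split {n} cases into {n_parts} non-empty parts")

    quotas = [f * n for f in fractions]
    sizes = [int(q) for q in quotas]
    remainders = [q - s for q, s in zip(quotas, sizes)]
    while sum(sizes) < n:  # largest remainder first; ties to the earlier part
        k = int(np.argmax(remainders))
        sizes[k] += 1
        remainders[k] = -1.0
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5B71]))
    order = list(case_ids)
    rng.shuffle(order)
    train_ids = sorted(order[: sizes[0]])
    val_ids = sorted(order[sizes[0]: sizes[0] + sizes[1]])
    test_ids = sorted(order[sizes[0] + sizes[1]:])
    return train_ids, val_ids, test_ids


def assert_no_leakage(training_candidates, test_case_ids) -> None:
    """Raise if any candidate of a test case reached the training stream."""
    test_set = set(test_case_ids)
    leaked = sorted({c.case_id for c in training_candidates} & test_set)
    if leaked:
        raise RuntimeError(f"test cases leaked into training: {leaked}")


@dataclass
class ExperimentConfig:
    """Everything one experiment needs, seeded."""

    phantom: phantom.PhantomConfig = field(default_factory=phantom.PhantomConfig)
    n_cases: int = 20
    split_fractions: tuple[float, float, float] = (0.8, 0.0, 0.2)
    target_spacing_mm: float = preprocess.DEFAULT_TARGET_SPACING_MM
    scales_mm: tuple[float, ...] = enhance.DEFAULT_SCALES_MM
    candidate_params: enhance.CandidateParams = field(default_factory=enhance.CandidateParams)
    patch_side: int = 32
    net: NetConfig = field(default_factory=NetConfig)
    archs: tuple[str, ...] = ("2d", "3d", "md")
    tau: float = 0.5
    min_votes: int = 6
    min_separation_vox: float = 16.0
    prefilter: bool = True
    prefilter_at_inference: bool = True
    seed: int = 0
    out_dir: str | None = None


def small_study_config(seed: int, n_cases: int = 50) -> ExperimentConfig:
    """The scaled-down phantom study used for end-to-end evaluation.

    50 cases (40 train / 10 test at the default 80/20 split), 64^3 voxels
    at the standard 0.3906 mm spacing (a 25 mm field of view), three
    vessels and two 3-6 mm aneurysms per case.  Candidate points are
    sparse blob-response maxima, so the vote minimum is 2 (the clinical
    default of 6 presumes the much denser candidate fields of full-size
    volumes); patch side 24 voxels (9.4 mm) contains any study aneurysm.

    The feature pre-filter stage is disabled here: on these clean phantoms
    the hand-crafted shape features alone separate the classes almost
    perfectly, which would starve the classifiers of negative training
    examples and collapse the architecture comparison the study exists to
    make.  The pre-filter keeps its own dedicated tests.
    """
    ph = phantom.PhantomConfig(
        volume_shape=(64, 64, 64),
        n_vessels=3,
        vessel_radius_range_mm=(0.6, 1.2),
        n_aneurysms=2,
        aneurysm_diameter_range_mm=(3.0, 6.0),
        seed=seed,
    )
    net = NetConfig(
        patch_side=24,
        branch_depth=2,
        base_channels=8,
        se_reduction=8,
        learning_rate=2e-3,
        batch_size=32,
        epochs=10,
        seed=seed,
    )
    return ExperimentConfig(
        phantom=ph,
        n_cases=n_cases,
        scales_mm=(0.8, 1.2, 1.8, 2.7),
        candidate_params=enhance.CandidateParams(
            min_response_percentile=30.0, nms_radius_mm=0.8, max_candidates=60
        ),
        patch_side=24,
        net=net,
        tau=0.5,
        min_votes=2,
        min_separation_vox=16.0,
        prefilter=False,
        seed=seed,
    )


def _prepare_case(vol, vessel_mask, anns, case_id, config, scale):
    """Normalize one case and extract labeled, featurized candidates."""
    vol = preprocess.resample_isotropic(vol, config.target_spacing_mm)
    norm = preprocess.nyul_apply(vol, scale)
    art = preprocess.extract_arteries(norm)
    search_mask = ndimage.binary_dilation(art.artery_mask, iterations=2)
    resp = enhance.shape_filter(norm, config.scales_mm, mask=search_mask)
    pts = enhance.extract_candidate_points(resp, art.artery_mask, config.candidate_params)
    cands = enhance.crop_and_label(norm, pts, anns, config.patch_side)
    for c in cands:
        enhance.candidate_features(c, resp, art.artery_mask)
        c.case_id = case_id
    return {
        "case_id": case_id,
        "candidates": cands,
        "artery_mask": art.artery_mask,
        "annotations": anns,
        "threshold_used": art.threshold_used,
    }


def run_experiment(config: ExperimentConfig) -> dict:
    """Run the full pipeline for every requested architecture on one split.

    Returns a results bundle: the split, per-arch training history, FROC
    curve, operating points, stratified tables and detection records.
    When ``config.out_dir`` is set, CSV/JSON artifacts and a seed manifest
    are written there.
    """
    cases_raw, manifest = phantom.generate_cohort(
        config.n_cases, config.phantom, config.seed
    )
    case_ids = [entry["case_id"] for entry in manifest["cases"]]
    train_ids, val_ids, test_ids = split_cases(
        case_ids, config.split_fractions, config.seed
    )
    fit_ids = set(train_ids) | set(val_ids)

    # intensity scale is trained on training-side volumes only
    scale = preprocess.nyul_train(
        [preprocess.resample_isotropic(v, config.target_spacing_mm)
         for (v, _, _), cid in zip(cases_raw, case_ids) if cid in fit_ids]
    )

    cases = {}
    for (vol, vessel_mask, anns), cid in zip(cases_raw, case_ids):
        cases[cid] = _prepare_case(vol, vessel_mask, anns, cid, config, scale)
    del cases_raw

    def _collect(ids):
        return [c for cid in ids for c in cases[cid]["candidates"]]

    train_cands = _collect(train_ids) + _collect(val_ids)
    test_cands = _collect(test_ids)
    assert_no_leakage(train_cands, test_ids)

    prefilter = None
    if config.prefilter:
        prefilter = enhance.CandidatePrefilter(random_state=config.seed)
        prefilter.fit(train_cands)
        train_cands = enhance.prefilter_candidates(train_cands, prefilter)
        if config.prefilter_at_inference:
            for cid in test_ids:
                cases[cid]["candidates"] = enhance.prefilter_candidates(
                    cases[cid]["candidates"], prefilter
                )
    assert_no_leakage(train_cands, test_ids)

    results = {
        "split": {"train": train_ids, "val": val_ids, "test": test_ids},
        "n_candidates": {
            "train": len(train_cands),
            "test": sum(len(cases[cid]["candidates"]) for cid in test_ids),
        },
        "manifest": {"seed": config.seed, "cases": manifest["cases"]},
        "archs": {},
    }

    for arch in config.archs:
        net_cfg = replace(config.net, patch_side=config.patch_side,
                          seed=config.net.seed)
        model = ClassifierModel(arch, net_cfg)
        model, history = train(model, train_cands, net_cfg)

        froc_cases = []
        det_records = []
        for cid in test_ids:
            case = cases[cid]
            predict(model, case["candidates"])
            dets = agg.detect_case(
                case["candidates"], case["artery_mask"],
                tau=config.tau, min_votes=config.min_votes,
                min_separation_vox=config.min_separation_vox, case_id=cid,
            )
            froc_cases.append((dets, case["annotations"]))
            det_records.extend(d.to_record() for d in dets)

        curve = froc.froc_curve(froc_cases)
        ops = froc.operating_points(curve)
        strat = froc.stratified_report(froc_cases)
        results["archs"][arch] = {
            "history": history,
            "best_val_loss": history["best_val_loss"],
            "constant_predictor_loss": constant_predictor_loss(train_cands, train_cands),
            "froc": curve,
            "operating_points": ops,
            "stratified": strat,
            "detections": det_records,
        }

    if config.out_dir:
        _write_bundle(results, config)
    return results


def _write_bundle(results: dict, config: ExperimentConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = {"split": results["split"], "n_candidates": results["n_candidates"],
               "seed": config.seed, "archs": {}}
    froc.plot_froc({arch: r["froc"] for arch, r in results["archs"].items()},
                   out / "froc.png")
    for arch, r in results["archs"].items():
        r["froc"].as_frame().to_csv(out / f"froc_{arch}.csv", index=False)
        r["stratified"]["by_size"].to_csv(out / f"stratified_size_{arch}.csv")
        r["stratified"]["by_location"].to_csv(out / f"stratified_location_{arch}.csv")
        (out / f"detections_{arch}.json").write_text(
            json.dumps(r["detections"], indent=2)
        )
        summary["archs"][arch] = {
            "operating_points": r["operating_points"],
            "best_val_loss": r["best_val_loss"],
            "constant_predictor_loss": r["constant_predictor_loss"],
        }
    cfg = asdict(config)
    cfg["phantom"] = asdict(config.phantom)
    (out / "experiment.json").write_text(json.dumps(
        {"summary": summary, "config": cfg}, indent=2, default=str))
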
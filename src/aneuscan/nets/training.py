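"""Training, prediction and cross-validation for the candidate classifiers.

Candidates labeled *positive*/*negative* (partials are discarded upstream)
are turned into model inputs — the raw S^3 patch for the 3D branch and the
multi-view MIP panel for the 2D branch (built lazily and cached on the
candidate) — and fitted with Adam on weighted binary cross-entropy.  The
positive class weight defaults to the inverse prevalence.  Per-epoch train
and validation losses are recorded and the best-validation weights are
restored at the end, so the returned model is the checkpoint that tracked
generalization, not the last iterate.  All randomness (shuffling, dropout,
init) flows from ``config.seed``; repeated runs are bit-identical.
"""

from __future__ import annotations

import numpy as np

from .. import mipgen
from ._layers import Adam, bce_with_logits
from .models import ClassifierModel, NetConfig

__all__ = ["train", "predict", "cross_validate", "prepare_inputs",
           "constant_predictor_loss"]


def _panel_of(candidate) -> np.ndarray:
    if candidate.panel is None:
        candidate.panel = mipgen.build_panel(candidate.patch).image
    return candidate.panel


def prepare_inputs(candidates, arch: str, input_scale: float) -> dict:
    """Stack candidate patches/panels into channels-first batches."""
    out = {}
    if arch in ("3d", "md"):
        out["patch"] = np.stack([c.patch for c in candidates])[:, None] / input_scale
    if arch in ("2d", "md"):
        out["panel"] = np.stack([_panel_of(c) for c in candidates])[:, None] / input_scale
    return out


def _labels(candidates) -> np.ndarray:
    return np.array([1.0 if c.label == "positive" else 0.0 for c in candidates])


def _split_train_val(candidates, val_fraction, rng):
    """Case-level holdout when case ids are present, candidate-level otherwise."""
    cases = sorted({c.case_id for c in candidates})
    if len(cases) >= 3:
        cases = list(cases)
        rng.shuffle(cases)
        n_val = max(1, int(round(val_fraction * len(cases))))
        val_cases = set(cases[:n_val])
        train = [c for c in candidates if c.case_id not in val_cases]
        val = [c for c in candidates if c.case_id in val_cases]
    else:
        idx = rng.permutation(len(candidates))
        n_val = max(1, int(round(val_fraction * len(candidates))))
        val_idx = set(idx[:n_val].tolist())
        train = [c for i, c in enumerate(candidates) if i not in val_idx]
        val = [c for i, c in enumerate(candidates) if i in val_idx]
    if not train or not val:
        raise ValueError("too few candidates for a train/validation split")
    return train, val


_FLIPS = [(), (2,), (3,), (2, 3), (4,), (2, 4), (3, 4), (2, 3, 4)]


def _augment_patch(patch, rng):
    """Random axis flips and a random 90-degree rotation of a cubic patch."""
    p = patch
    axes = _FLIPS[rng.integers(len(_FLIPS))]
    for ax in axes:
        p = np.flip(p, axis=ax - 2)
    k = int(rng.integers(4))
    if k:
        p = np.rot90(p, k=k, axes=(0, 1))
    return np.ascontiguousarray(p)


def evaluate_loss(model: ClassifierModel, candidates, batch_size=64) -> float:
    """Mean unweighted BCE of the model on labeled candidates."""
    y = _labels(candidates)
    losses, ns = [], []
    for i in range(0, len(candidates), batch_size):
        chunk = candidates[i:i + batch_size]
        logits = model.forward_logits(
            prepare_inputs(chunk, model.arch, model.config.input_scale), train=False
        )
        loss, _ = bce_with_logits(logits, y[i:i + len(chunk)])
        losses.append(loss)
        ns.append(len(chunk))
    return float(np.average(losses, weights=ns))


def constant_predictor_loss(train_candidates, eval_candidates) -> float:
    """BCE of the best constant probability (the training prevalence) on the
    evaluation set — the 'learned nothing' baseline."""
    p = float(np.clip(_labels(train_candidates).mean(), 1e-7, 1 - 1e-7))
    y = _labels(eval_candidates)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


def train(
    model: ClassifierModel,
    candidates,
    config: NetConfig | None = None,
    val_candidates=None,
) -> tuple[ClassifierModel, dict]:
    """Fit a classifier on labeled candidates.

    Returns ``(model, history)`` where ``history`` has per-epoch
    ``train_loss`` and ``val_loss`` lists (length = epochs) and the model
    carries the weights of the best validation epoch.
    """
    config = config or model.config
    usable = [c for c in candidates if c.label in ("positive", "negative")]
    y_all = _labels(usable)
    if y_all.sum() == 0 or y_all.sum() == len(y_all):
        raise ValueError("training needs both positive and negative candidates")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x7A41]))
    if val_candidates is None:
        train_set, val_set = _split_train_val(usable, config.val_fraction, rng)
    else:
        train_set = usable
        val_set = [c for c in val_candidates if c.label in ("positive", "negative")]
    y_train = _labels(train_set)
    if y_train.sum() == 0 or y_train.sum() == len(y_train):
        raise ValueError("train split lost one class; provide val_candidates explicitly")

    if config.pos_weight == "auto":
        pos_w = float((len(y_train) - y_train.sum()) / max(y_train.sum(), 1.0))
    else:
        pos_w = float(config.pos_weight) if config.pos_weight else 1.0

    optimizer = Adam(model.params(), lr=config.learning_rate)
    history = {"train_loss": [], "val_loss": []}
    best = (np.inf, model.get_weights())

    for _epoch in range(config.epochs):
        order = rng.permutation(len(train_set))
        epoch_losses, epoch_ns = [], []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            chunk = [train_set[i] for i in idx]
            if config.augment:
                chunk = [_augmented_copy(c, rng) for c in chunk]
            yb = y_train[idx]
            wb = np.where(yb > 0.5, pos_w, 1.0)
            inputs = prepare_inputs(chunk, model.arch, config.input_scale)
            logits = model.forward_logits(inputs, train=True)
            loss, dlogits = bce_with_logits(logits, yb, wb)
            optimizer.zero_grad()
            model.backward(dlogits)
            optimizer.step()
            epoch_losses.append(loss)
            epoch_ns.append(len(idx))
        history["train_loss"].append(float(np.average(epoch_losses, weights=epoch_ns)))
        val_loss = evaluate_loss(model, val_set, batch_size=max(config.batch_size, 64))
        history["val_loss"].append(val_loss)
        if val_loss < best[0]:
            best = (val_loss, model.get_weights())

    model.set_weights(best[1])
    history["best_val_loss"] = float(best[0])
    return model, history


def _augmented_copy(candidate, rng):
    import copy

    c = copy.copy(c_orig := candidate)
    c.patch = _augment_patch(c_orig.patch, rng)
    c.panel = None  # panel must match the augmented patch
    return c


def predict(model: ClassifierModel, candidates, batch_size=64) -> np.ndarray:
    """Per-candidate probabilities; also stored on ``candidate.probability``."""
    probs = []
    for i in range(0, len(candidates), batch_size):
        chunk = candidates[i:i + batch_size]
        probs.append(model.predict_proba(
            prepare_inputs(chunk, model.arch, model.config.input_scale)))
    p = np.concatenate(probs) if probs else np.zeros(0)
    for c, pi in zip(candidates, p):
        c.probability = float(pi)
    return p


def cross_validate(candidates, config_grid, k: int = 4, arch: str = "md"):
    """Case-level k-fold hyperparameter selection.

    Cases are split into k folds (each case validates exactly once); every
    config in the grid is trained on k-1 folds and scored on the held-out
    fold; the config with the lowest mean validation loss wins.
    """
    config_grid = list(config_grid)
    if not config_grid:
        raise ValueError("config grid is empty")
    cases = sorted({c.case_id for c in candidates})
    if len(cases) < k:
        raise ValueError(f"need at least k={k} cases, got {len(cases)}")
    rng = np.random.default_rng(np.random.SeedSequence([config_grid[0].seed, 0xCF]))
    cases = list(cases)
    rng.shuffle(cases)
    folds = [set(f) for f in np.array_split(np.array(cases, dtype=object), k)]

    results = []
    for config in config_grid:
        fold_losses = []
        for fold in folds:
            tr = [c for c in candidates if c.case_id not in fold]
            va = [c for c in candidates if c.case_id in fold]
            model = ClassifierModel(arch, config)
            _, hist = train(model, tr, config, val_candidates=va)
            fold_losses.append(hist["best_val_loss"])
        results.append(float(np.mean(fold_losses)))
    best_idx = int(np.argmin(results))
    return config_grid[best_idx], {"mean_val_losses": results, "folds": folds}
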
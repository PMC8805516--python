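"""The three candidate classifiers: planar (2D), stereoscopic (3D), fused (MD).

Each branch is a stack of squeeze-and-excitation residual stages over a
single-channel input — the 2D branch consumes the vertically concatenated
(n_views*S, S) MIP panel, the 3D branch the raw S^3 intensity patch — ending
in global average pooling.  A stand-alone model attaches a single-logit
dense head to one branch; the multidimensional (MD) model concatenates the
pooled feature vectors of both branches and feeds them to one fresh dense
head, so its parameter count is exactly branch(2D) + branch(3D) + head.
Both MD branches are trained simultaneously from scratch; there is no
weight sharing or pre-training.

Outputs are probabilities in [0, 1] via a sigmoid on the head logit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from ._layers import (
    Conv, Dense, Dropout, GlobalAvgPool, ReLU, ResBlock, Sequential, sigmoid,
)

__all__ = ["NetConfig", "ClassifierModel", "build_2d", "build_3d", "build_md"]


@dataclass
class NetConfig:
    """Architecture and optimization settings for one classifier.

    ``branch_depth`` SE-residual stages; stage ``i`` has
    ``base_channels * 2**i`` channels and stride 2, so spatial extent
    halves per stage.  ``input_scale`` divides raw intensities (the
    standardized scale tops out near 100) so inputs are O(1).
    """

    patch_side: int = 32
    n_views: int = 15
    branch_depth: int = 3
    base_channels: int = 16
    se_reduction: int = 16
    dropout: float = 0.0
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 10
    loss: str = "bce"
    seed: int = 0
    input_scale: float = 100.0
    pos_weight: str | float | None = "auto"
    augment: bool = False
    val_fraction: float = 0.2

    def __post_init__(self):
        for name in ("patch_side", "n_views", "branch_depth", "base_channels",
                     "se_reduction", "batch_size", "epochs"):
            if int(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.base_channels % self.se_reduction:
            raise ValueError(
                f"se_reduction ({self.se_reduction}) must divide base_channels "
                f"({self.base_channels}) so every stage width is divisible"
            )
        if self.loss != "bce":
            raise ValueError("only binary cross-entropy ('bce') is supported")
        if self.patch_side // 2 ** (self.branch_depth + 0) < 1:
            raise ValueError(
                f"patch_side {self.patch_side} too small for {self.branch_depth} "
                f"halving stages"
            )

    def to_dict(self) -> dict:
        return asdict(self)


def _branch(ndim: int, config: NetConfig, rng) -> tuple[Sequential, int]:
    # stride-2 stem: halves every spatial dim before the residual stages
    layers = [Conv(1, config.base_channels, ndim, kernel=3, stride=2, rng=rng), ReLU()]
    ch = config.base_channels
    for i in range(config.branch_depth):
        out_ch = config.base_channels * 2**i
        layers.append(ResBlock(ch, out_ch, ndim, config.se_reduction, stride=2, rng=rng))
        ch = out_ch
    layers.append(GlobalAvgPool())
    return Sequential(layers), ch


class ClassifierModel:
    """A trained/trainable candidate classifier (arch '2d', '3d' or 'md')."""

    def __init__(self, arch: str, config: NetConfig):
        if arch not in ("2d", "3d", "md"):
            raise ValueError(f"unknown arch {arch!r}")
        self.arch = arch
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x2E75]))
        self.branch_2d = self.branch_3d = None
        feat = 0
        if arch in ("2d", "md"):
            self.branch_2d, f2 = _branch(2, config, rng)
            feat += f2
        if arch in ("3d", "md"):
            self.branch_3d, f3 = _branch(3, config, rng)
            feat += f3
        self.dropout = Dropout(config.dropout,
                               np.random.default_rng(np.random.SeedSequence([config.seed, 0xD0])))
        self.head = Dense(feat, 1, rng)

    # -- parameters -----------------------------------------------------------
    def params(self):
        ps = []
        for br in (self.branch_2d, self.branch_3d):
            if br is not None:
                ps += br.params()
        return ps + self.head.params()

    def num_params(self) -> int:
        return sum(p.size for p in self.params())

    def num_branch_params(self) -> int:
        return self.num_params() - sum(p.size for p in self.head.params())

    def get_weights(self):
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights):
        for p, w in zip(self.params(), weights):
            p.value[...] = w

    # -- forward / backward ---------------------------------------------------
    def _features(self, inputs, train):
        feats = []
        if self.branch_2d is not None:
            feats.append(self.branch_2d.forward(inputs["panel"], train))
        if self.branch_3d is not None:
            feats.append(self.branch_3d.forward(inputs["patch"], train))
        self._feat_widths = [f.shape[1] for f in feats]
        return np.concatenate(feats, axis=1)

    def forward_logits(self, inputs, train: bool = False) -> np.ndarray:
        f = self._features(inputs, train)
        return self.head.forward(self.dropout.forward(f, train), train)[:, 0]

    def backward(self, dlogits) -> None:
        df = self.dropout.backward(self.head.backward(dlogits[:, None]))
        start = 0
        for br, width in zip(
            [b for b in (self.branch_2d, self.branch_3d) if b is not None],
            self._feat_widths,
        ):
            br.backward(df[:, start:start + width])
            start += width

    def predict_proba(self, inputs) -> np.ndarray:
        """Per-candidate aneurysm probability; pure function of (weights, input)."""
        return sigmoid(self.forward_logits(inputs, train=False))

    # -- persistence ----------------------------------------------------------
    def save(self, path) -> None:
        import json
        from pathlib import Path

        path = Path(path)
        arrays = {f"w{i}": w for i, w in enumerate(self.get_weights())}
        np.savez(path.with_suffix(".npz"), **arrays)
        sidecar = {"arch": self.arch, "config": self.config.to_dict()}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "ClassifierModel":
        import json
        from pathlib import Path

        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        model = cls(sidecar["arch"], NetConfig(**sidecar["config"]))
        with np.load(path.with_suffix(".npz")) as data:
            model.set_weights([data[f"w{i}"] for i in range(len(data.files))])
        return model


def build_2d(config: NetConfig) -> ClassifierModel:
    """Planar classifier over the concatenated multi-view MIP panel."""
    return ClassifierModel("2d", config)


def build_3d(config: NetConfig) -> ClassifierModel:
    """Stereoscopic classifier over the raw cubic intensity patch."""
    return ClassifierModel("3d", config)


def build_md(config: NetConfig) -> ClassifierModel:
    """Fused two-input classifier: concatenated pooled branch features into
    a single fully connected probability head."""
    return ClassifierModel("md", config)
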
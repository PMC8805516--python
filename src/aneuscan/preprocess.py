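"""Volume normalization: isotropic resampling, histogram-landmark intensity
standardization (Nyul–Udupa), and three-sigma artery thresholding.

MR signal values have no absolute scale, and multi-scanner studies need a
common intensity frame before any fixed threshold is meaningful.  The
standardization used here is the classic landmark method: each volume's
decile percentiles are piecewise-linearly mapped onto a standard scale
learned as the across-volume mean of the (affinely anchored) landmarks.
After standardization, voxels above the volume's mean + 3 standard
deviations are taken as artery — in a bright-vessel angiogram the arteries
are precisely the upper intensity tail.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import Volume

__all__ = [
    "StandardScale",
    "ArteryVolume",
    "resample_isotropic",
    "nyul_train",
    "nyul_apply",
    "extract_arteries",
]

DEFAULT_TARGET_SPACING_MM = 0.3906
DEFAULT_LANDMARKS = tuple(float(p) for p in range(10, 100, 10))  # deciles
DEFAULT_CLIP_BOUNDS = (1.0, 99.0)
STANDARD_RANGE = (0.0, 100.0)


@dataclass
class StandardScale:
    """A trained piecewise-linear intensity standardization.

    ``landmark_percentiles`` are interior landmarks (deciles by default);
    ``standard_values`` are their positions on the standard scale, learned
    by :func:`nyul_train`.  ``clip_bounds`` are the percentiles anchored to
    the ends of the standard range; intensities outside them are clamped.
    """

    landmark_percentiles: tuple[float, ...] = DEFAULT_LANDMARKS
    standard_values: tuple[float, ...] = ()
    clip_bounds: tuple[float, float] = DEFAULT_CLIP_BOUNDS
    standard_range: tuple[float, float] = STANDARD_RANGE

    def __post_init__(self) -> None:
        lp = np.asarray(self.landmark_percentiles, dtype=float)
        if lp.size == 0 or np.any(np.diff(lp) <= 0):
            raise ValueError("landmark_percentiles must be strictly increasing and non-empty")
        if not (0 < self.clip_bounds[0] < lp[0] and lp[-1] < self.clip_bounds[1] < 100):
            raise ValueError("clip_bounds must strictly bracket the landmarks within (0, 100)")
        if self.standard_values and (
            len(self.standard_values) != lp.size
            or np.any(np.diff(self.standard_values) <= 0)
        ):
            raise ValueError("standard_values must match landmarks and be strictly increasing")

    @property
    def is_trained(self) -> bool:
        return len(self.standard_values) > 0

    # -- serialization (JSON) -------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "landmark_percentiles": list(self.landmark_percentiles),
                "standard_values": list(self.standard_values),
                "clip_bounds": list(self.clip_bounds),
                "standard_range": list(self.standard_range),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "StandardScale":
        d = json.loads(text)
        return cls(
            tuple(d["landmark_percentiles"]),
            tuple(d["standard_values"]),
            tuple(d["clip_bounds"]),
            tuple(d["standard_range"]),
        )


@dataclass
class ArteryVolume:
    """A standardized volume with its artery mask and the threshold used."""

    volume: Volume
    artery_mask: np.ndarray
    threshold_used: float
    meta: dict = field(default_factory=dict)


def resample_isotropic(volume: Volume, target_spacing_mm: float = DEFAULT_TARGET_SPACING_MM) -> Volume:
    """Resample to an isotropic grid by trilinear interpolation.

    World position of voxel ``j`` on each axis is ``j * spacing``; output
    voxel ``j`` samples input coordinate ``j * target / source``.  Output
    shape is ``round(shape * source / target)`` per axis, preserving the
    world extent to within one output voxel.
    """
    if target_spacing_mm <= 0:
        raise ValueError("target spacing must be positive")
    src = volume.spacing_mm
    if all(abs(s - target_spacing_mm) < 1e-9 for s in src):
        return Volume(volume.data.copy(), target_spacing_mm, dict(volume.meta))
    out_shape = tuple(
        max(1, int(round(n * s / target_spacing_mm))) for n, s in zip(volume.shape, src)
    )
    axes = [np.arange(n_out) * target_spacing_mm / s for n_out, s in zip(out_shape, src)]
    coords = np.meshgrid(*axes, indexing="ij")
    data = ndimage.map_coordinates(
        np.asarray(volume.data, dtype=np.float32), coords, order=1, mode="nearest"
    )
    meta = dict(volume.meta)
    meta["resampled_from_spacing_mm"] = src
    return Volume(data, target_spacing_mm, meta)


def _landmarks(data: np.ndarray, scale: StandardScale) -> tuple[float, float, np.ndarray]:
    flat = np.asarray(data, dtype=np.float64).ravel()
    lo, hi = np.percentile(flat, scale.clip_bounds)
    if hi <= lo:
        raise ValueError("degenerate intensity histogram (constant volume?)")
    return float(lo), float(hi), np.percentile(flat, scale.landmark_percentiles)


def nyul_train(volumes: list[Volume], scale_spec: StandardScale | None = None) -> StandardScale:
    """Learn the standard intensity scale from training volumes.

    Each volume's clip-bound percentiles are affinely anchored to the
    standard range, its landmark percentiles mapped through that affine,
    and the standard values are the across-volume means of the anchored
    landmarks.
    """
    if not volumes:
        raise ValueError("nyul_train needs at least one training volume")
    spec = scale_spec or StandardScale()
    s_lo, s_hi = spec.standard_range
    anchored = []
    for vol in volumes:
        lo, hi, lms = _landmarks(vol.data, spec)
        anchored.append(s_lo + (lms - lo) * (s_hi - s_lo) / (hi - lo))
    standard = np.mean(anchored, axis=0)
    return StandardScale(
        spec.landmark_percentiles, tuple(float(v) for v in standard),
        spec.clip_bounds, spec.standard_range,
    )


def nyul_apply(volume: Volume, scale: StandardScale) -> Volume:
    """Map a volume onto the standard scale.

    Piecewise-linear, monotone: the volume's clip-bound percentiles go to
    the ends of the standard range, its landmark percentiles to
    ``standard_values``, and values outside the clip bounds are clamped.
    Applying it to a volume already on the standard scale is the identity
    at the landmarks (and hence idempotent).
    """
    if not scale.is_trained:
        raise ValueError("StandardScale is untrained: run nyul_train first")
    lo, hi, lms = _landmarks(volume.data, scale)
    xp = np.concatenate([[lo], lms, [hi]])
    fp = np.concatenate([[scale.standard_range[0]], scale.standard_values,
                         [scale.standard_range[1]]])
    if np.any(np.diff(xp) <= 0):
        raise ValueError("volume landmarks are not strictly increasing (flat histogram)")
    data = np.interp(np.asarray(volume.data, dtype=np.float64), xp, fp)
    meta = dict(volume.meta)
    meta["intensity_standardized"] = True
    return Volume(data.astype(np.float32), volume.spacing_mm, meta)


def extract_arteries(volume: Volume, foreground_min: float = 0.0) -> ArteryVolume:
    """Threshold a standardized volume at mean + 3*sigma to keep arteries.

    Statistics are computed over voxels with intensity > ``foreground_min``
    (excludes padding introduced by resampling).  A constant volume has
    sigma = 0; keeping everything would flood downstream candidate
    extraction, so the degenerate case returns an empty mask with a warning.
    """
    data = np.asarray(volume.data, dtype=np.float64)
    fg = data[data > foreground_min]
    if fg.size == 0:
        warnings.warn("no foreground voxels above %g; artery mask is empty" % foreground_min)
        return ArteryVolume(volume, np.zeros(volume.shape, dtype=bool), float("inf"))
    mu, sd = float(fg.mean()), float(fg.std())
    if sd == 0.0:
        warnings.warn("constant volume: sigma = 0, artery mask left empty")
        return ArteryVolume(volume, np.zeros(volume.shape, dtype=bool), float("inf"),
                            {"degenerate": True})
    thr = mu + 3.0 * sd
    mask = data >= thr
    return ArteryVolume(volume, mask, thr, {"mean": mu, "std": sd})
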
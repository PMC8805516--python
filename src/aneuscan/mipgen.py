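"""15-view maximum-intensity-projection panels for the planar classifier.

A cubic candidate patch is viewed from 15 deterministic orientations: the
three canonical axis projections plus rotations of +/-30 and +/-45 degrees
about each of the X, Y and Z axes.  Each view is resampled under its
rotation (trilinear, zero-padded), projected by per-ray maximum along the
first array axis, and the 15 square tiles are concatenated vertically into
a single (15*S, S) image.  No per-tile rescaling is applied, so relative
brightness across views is preserved.

The orientation enumeration lives in one function so an alternative
15-view convention is a one-line change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["Orientation", "MIPPanel", "orientation_set", "mip_project", "build_panel",
           "N_VIEWS"]

N_VIEWS = 15


@dataclass(frozen=True)
class Orientation:
    name: str
    rotation: np.ndarray  # 3x3 proper rotation applied to the patch

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")


@dataclass
class MIPPanel:
    """Vertically concatenated square MIP tiles, one per orientation."""

    image: np.ndarray
    view_order: tuple[str, ...]

    @property
    def n_views(self) -> int:
        return len(self.view_order)

    def tile(self, k: int) -> np.ndarray:
        s = self.image.shape[1]
        return self.image[k * s:(k + 1) * s]


def _axis_rotation(axis: int, degrees: float) -> np.ndarray:
    c, s = np.cos(np.radians(degrees)), np.sin(np.radians(degrees))
    if axis == 0:
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)
    if axis == 1:
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)


def orientation_set() -> list[Orientation]:
    """The fixed, ordered 15-view set.

    Views 0-2 are the unrotated axial/coronal/sagittal projections (the
    projection axis is always the first array axis, so the coronal and
    sagittal views are expressed as 90-degree proper rotations bringing the
    second and third axes into projection position).  Views 3-14 rotate the
    patch by +/-30 and +/-45 degrees about X, Y and Z.
    """
    views = [
        Orientation("axial", np.eye(3)),
        Orientation("coronal", _axis_rotation(2, 90.0)),
        Orientation("sagittal", _axis_rotation(1, -90.0)),
    ]
    for axis, axis_name in ((0, "x"), (1, "y"), (2, "z")):
        for deg in (30.0, -30.0, 45.0, -45.0):
            sign = "+" if deg > 0 else "-"
            views.append(Orientation(f"rot{axis_name}{sign}{abs(deg):.0f}",
                                     _axis_rotation(axis, deg)))
    assert len(views) == N_VIEWS
    return views


def mip_project(patch: np.ndarray, orientation: Orientation) -> np.ndarray:
    """Maximum-intensity projection of a cubic patch under one orientation.

    The patch is rotated about its center (trilinear interpolation), then
    reduced by max along the first axis.  Out-of-patch samples take the
    patch minimum, so every tile pixel stays within the patch's intensity
    range (for background-zero patches this is plain zero padding).
    """
    patch = np.asarray(patch, dtype=np.float32)
    if patch.ndim != 3 or len(set(patch.shape)) != 1:
        raise ValueError(f"mip_project needs a cubic patch, got shape {patch.shape}")
    R = np.asarray(orientation.rotation, dtype=float)
    if np.allclose(R, np.eye(3)):
        rotated = patch
    else:
        center = (np.asarray(patch.shape) - 1) / 2.0
        # output voxel x samples input R^-1 (x - c) + c ; R^-1 = R.T
        rotated = ndimage.affine_transform(
            patch, R.T, offset=center - R.T @ center, order=1,
            mode="constant", cval=float(patch.min()),
        )
    return rotated.max(axis=0)


def build_panel(patch: np.ndarray, views: list[Orientation] | None = None) -> MIPPanel:
    """Concatenate all views' MIP tiles vertically into one (n*S, S) image."""
    views = views if views is not None else orientation_set()
    tiles = [mip_project(patch, v) for v in views]
    return MIPPanel(np.concatenate(tiles, axis=0), tuple(v.name for v in views))
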
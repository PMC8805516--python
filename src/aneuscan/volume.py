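"""Core containers for volumetric angiography data.

A :class:`Volume` is the unit every pipeline stage consumes and produces: a
3D intensity grid with an isotropic (or per-axis) voxel spacing in mm and a
free-form metadata dict.  World coordinates are axis-aligned: the physical
position of voxel ``(i, j, k)`` is ``(i, j, k) * spacing`` — no oblique
affine support.

An :class:`AnnotationSet` carries per-aneurysm ground truth: a boolean voxel
mask, the centroid, the mask-derived equivalent diameter in mm and a
location label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["Volume", "Annotation", "AnnotationSet", "equivalent_diameter_mm"]


def equivalent_diameter_mm(mask: np.ndarray, spacing_mm: float) -> float:
    """Diameter of the sphere with the same volume as ``mask``.

    ``d = (6 V / pi)^(1/3) * spacing`` with ``V`` the voxel count, so the
    value is recomputable from the mask alone.
    """
    v = int(np.count_nonzero(mask))
    return float((6.0 * v / np.pi) ** (1.0 / 3.0) * spacing_mm)


@dataclass
class Volume:
    """3D intensity grid plus isotropic voxel spacing (mm) and provenance."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        if np.isscalar(self.spacing_mm):
            s = float(self.spacing_mm)
            self.spacing_mm = (s, s, s)
        else:
            self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def is_isotropic(self) -> bool:
        s = self.spacing_mm
        return abs(s[0] - s[1]) < 1e-9 and abs(s[1] - s[2]) < 1e-9

    @property
    def spacing(self) -> float:
        """Scalar spacing; raises if the volume is anisotropic."""
        if not self.is_isotropic:
            raise ValueError(f"volume is anisotropic: {self.spacing_mm}")
        return self.spacing_mm[0]

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.spacing_mm
        return aff

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine())
        img.header.set_zooms(self.spacing_mm)
        return img

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path) -> "Volume":
        img = nib.load(str(path))
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asarray(img.dataobj, dtype=np.float32), zooms, {"source": str(path)})


@dataclass
class Annotation:
    """One aneurysm: mask in volume voxel space, centroid, size, location."""

    id: int
    mask: np.ndarray
    centroid_ijk: tuple[float, float, float]
    equivalent_diameter_mm: float
    location_label: str = ""

    def bounding_box(self) -> tuple[tuple[int, int], ...]:
        """Tight half-open per-axis bounds ``((lo, hi), ...)`` of the mask."""
        idx = np.nonzero(self.mask)
        return tuple((int(ax.min()), int(ax.max()) + 1) for ax in idx)


@dataclass
class AnnotationSet:
    """Per-aneurysm ground truth for one volume.

    Masks must be non-empty and pairwise disjoint; the equivalent diameter is
    recomputable from each mask via :func:`equivalent_diameter_mm`.
    """

    regions: list[Annotation] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def validate(self, spacing_mm: float | None = None) -> None:
        seen = None
        for ann in self.regions:
            if not ann.mask.any():
                raise ValueError(f"annotation {ann.id} has an empty mask")
            if seen is None:
                seen = np.zeros_like(ann.mask, dtype=bool)
            if (seen & ann.mask).any():
                raise ValueError(f"annotation {ann.id} overlaps a previous one")
            seen |= ann.mask
            if spacing_mm is not None:
                d = equivalent_diameter_mm(ann.mask, spacing_mm)
                if abs(d - ann.equivalent_diameter_mm) > 1e-6:
                    raise ValueError(
                        f"annotation {ann.id}: stored diameter "
                        f"{ann.equivalent_diameter_mm:.4f} != mask-derived {d:.4f}"
                    )

    def label_volume(self) -> np.ndarray:
        """Integer label map (0 background, annotation ids elsewhere)."""
        if not self.regions:
            raise ValueError("empty annotation set has no reference grid")
        out = np.zeros(self.regions[0].mask.shape, dtype=np.int16)
        for ann in self.regions:
            out[ann.mask] = ann.id
        return out

    def to_table(self) -> list[dict]:
        return [
            {
                "id": ann.id,
                "centroid_ijk": [float(c) for c in ann.centroid_ijk],
                "diameter_mm": float(ann.equivalent_diameter_mm),
                "location": ann.location_label,
            }
            for ann in self.regions
        ]
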
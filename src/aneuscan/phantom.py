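"""Synthetic TOF-MRA-like vascular phantoms with implanted aneurysms.

Clinical time-of-flight MR angiography shows arteries as bright tubes on a
darker noisy background; saccular aneurysms are roughly spherical bulges on
the vessel wall.  This module generates seeded volumes that emulate exactly
those features — smooth spline-centerline tubes with bifurcations and
curvature, Gaussian cross-section intensity profiles, additive Gaussian
background noise, and spherical bright bulges attached to vessel walls —
together with per-aneurysm ground-truth masks, so every downstream stage
(thresholding, Hessian filtering, candidate classification, FROC scoring)
is testable without patient data.

Everything is a deterministic function of ``(config, seed)``: independent
random streams (structure / noise / implant) are spawned from the config
seed, so e.g. regenerating with ``noise_sigma=0`` yields the identical
noiseless signal component.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline

from .volume import Annotation, AnnotationSet, Volume, equivalent_diameter_mm

__all__ = [
    "PhantomConfig",
    "generate_vessel_volume",
    "implant_aneurysms",
    "generate_phantom",
    "generate_cohort",
]

# Aneurysms larger than this are outside the generator's remit (clinically
# they are not a detection-software problem: radiologists do not miss them).
MAX_ANEURYSM_DIAMETER_MM = 15.0


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for one synthetic volume.

    Intensities are arbitrary signal units; the defaults give vessels a
    contrast of ~16 noise sigmas over background, a comfortably bright-artery
    regime comparable to a clean TOF acquisition after windowing.
    """

    volume_shape: tuple[int, int, int] = (128, 128, 128)
    spacing_mm: float = 0.3906
    n_vessels: int = 3
    vessel_radius_range_mm: tuple[float, float] = (0.8, 2.0)
    n_aneurysms: int = 2
    aneurysm_diameter_range_mm: tuple[float, float] = (3.0, 15.0)
    vessel_intensity: float = 100.0
    background_mean: float = 20.0
    noise_sigma: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be positive")
        if len(self.volume_shape) != 3 or any(int(s) < 8 for s in self.volume_shape):
            raise ValueError(f"volume_shape must be 3 axes of >= 8 voxels, got {self.volume_shape}")
        for name in ("vessel_radius_range_mm", "aneurysm_diameter_range_mm"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must satisfy 0 < min <= max, got ({lo}, {hi})")
        if self.aneurysm_diameter_range_mm[1] > MAX_ANEURYSM_DIAMETER_MM:
            raise ValueError(
                f"aneurysm diameters above {MAX_ANEURYSM_DIAMETER_MM} mm are not simulated"
            )
        if self.n_vessels < 0 or self.n_aneurysms < 0:
            raise ValueError("n_vessels and n_aneurysms must be non-negative")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


def _sample_centerline(rng, shape, start, direction, length_vox, n_ctrl=6, wiggle=0.45,
                       margin=4.0):
    """A smooth C1 random curve: correlated random-walk control points
    interpolated by a cubic spline and densely resampled (~2 samples/voxel).
    The walk reflects off the volume faces so tubes keep most of their
    length inside the field of view."""
    pts = [np.asarray(start, dtype=float)]
    d = _unit(np.asarray(direction, dtype=float))
    step = length_vox / n_ctrl
    hi_lim = np.asarray(shape, dtype=float) - 1 - margin
    for _ in range(n_ctrl):
        d = _unit(d + wiggle * rng.standard_normal(3))
        nxt = pts[-1] + d * step
        for a in range(3):  # reflect off the faces
            if nxt[a] < margin or nxt[a] > hi_lim[a]:
                d[a] = -d[a]
        pts.append(pts[-1] + d * step)
    pts = np.array(pts)
    t = np.arange(len(pts), dtype=float)
    spl = CubicSpline(t, pts, axis=0)
    dense_t = np.linspace(0.0, t[-1], max(int(2 * length_vox), 8))
    dense = spl(dense_t)
    # clip to the volume: keep the longest in-bounds prefix from the start
    inside = np.all((dense >= 0) & (dense <= np.asarray(shape) - 1), axis=1)
    if not inside[0]:
        return dense[:0]
    stop = int(np.argmin(inside)) if not inside.all() else len(dense)
    return dense[:stop]


def generate_vessel_volume(config: PhantomConfig) -> tuple[Volume, np.ndarray]:
    """Render ``config.n_vessels`` bright tubes over Gaussian background noise.

    Vessel ``i >= 1`` branches off a randomly chosen point of an earlier
    vessel, so any phantom with two or more vessels contains at least one
    bifurcation — the classic false-positive source for blob detectors.

    Returns the noisy volume (with ``meta`` carrying the noiseless signal
    component, branch points and centerline endpoints) and the boolean tube
    interior mask.
    """
    shape = tuple(int(s) for s in config.volume_shape)
    spacing = config.spacing_mm
    max_r_vox = config.vessel_radius_range_mm[1] / spacing
    if config.n_vessels > 0 and 4 * max_r_vox + 2 >= min(shape):
        raise ValueError(
            f"volume of {min(shape)} voxels/axis cannot contain tubes of radius "
            f"{config.vessel_radius_range_mm[1]} mm ({max_r_vox:.1f} voxels) at "
            f"{spacing} mm spacing"
        )

    ss = np.random.SeedSequence([int(config.seed), 0x7E55E1])
    rng_structure, rng_noise = [np.random.default_rng(c) for c in ss.spawn(2)]

    signal = np.zeros(shape, dtype=np.float64)
    vessel_mask = np.zeros(shape, dtype=bool)
    centerlines: list[np.ndarray] = []
    branch_points: list[tuple[int, int, int]] = []
    endpoints: list[tuple[int, int, int]] = []

    for i in range(config.n_vessels):
        r_mm = rng_structure.uniform(*config.vessel_radius_range_mm)
        r_vox = r_mm / spacing
        if i == 0 or not centerlines:
            lo = 0.15 * np.asarray(shape)
            hi = 0.85 * np.asarray(shape)
            start = rng_structure.uniform(lo, hi)
            direction = rng_structure.standard_normal(3)
        else:
            parent = centerlines[rng_structure.integers(len(centerlines))]
            j = rng_structure.integers(int(0.2 * len(parent)), int(0.8 * len(parent)) + 1)
            start = parent[j]
            tangent = _unit(parent[min(j + 1, len(parent) - 1)] - parent[max(j - 1, 0)])
            direction = _unit(tangent + 1.2 * rng_structure.standard_normal(3))
            branch_points.append(tuple(int(round(c)) for c in start))
        line = _sample_centerline(
            rng_structure, shape, start, direction, length_vox=0.8 * min(shape)
        )
        if len(line) < 4:
            continue
        centerlines.append(line)
        endpoints.append(tuple(int(round(c)) for c in line[0]))
        endpoints.append(tuple(int(round(c)) for c in line[-1]))

        seed_grid = np.zeros(shape, dtype=bool)
        ijk = np.round(line).astype(int)
        seed_grid[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = True
        dist = ndimage.distance_transform_edt(~seed_grid)
        np.maximum(signal, config.vessel_intensity * np.exp(-(dist**2) / (2.0 * r_vox**2)),
                   out=signal)
        vessel_mask |= dist <= r_vox

    signal += config.background_mean
    noise = rng_noise.normal(0.0, config.noise_sigma, size=shape) if config.noise_sigma > 0 \
        else np.zeros(shape)
    vol = Volume(
        (signal + noise).astype(np.float32),
        spacing,
        meta={
            "signal": signal.astype(np.float32),
            "branch_points_ijk": branch_points,
            "endpoints_ijk": endpoints,
            "phantom_config": asdict(config),
        },
    )
    return vol, vessel_mask


def _location_label(center, meta, spacing_mm, near_mm=3.0) -> str:
    """Synthetic location vocabulary: bifurcation / distal / trunk."""
    center = np.asarray(center, dtype=float)
    for key, label in (("branch_points_ijk", "bifurcation"), ("endpoints_ijk", "distal")):
        pts = meta.get(key) or []
        if pts and np.min(np.linalg.norm(np.asarray(pts, float) - center, axis=1)) \
                * spacing_mm < near_mm:
            return label
    return "trunk"


def implant_aneurysms(
    volume: Volume, vessel_mask: np.ndarray, config: PhantomConfig
) -> tuple[Volume, AnnotationSet]:
    """Attach bright spherical bulges to vessel walls and return ground truth.

    Each bulge is a sphere of intensity ``vessel_intensity`` whose center
    sits one nominal vessel radius outward from a randomly chosen wall
    voxel along the local outward normal, giving a hemispheric protrusion.
    Equivalent diameters are drawn uniformly from
    ``config.aneurysm_diameter_range_mm``; the returned masks are pairwise
    disjoint and entirely inside the volume.
    """
    if config.n_aneurysms == 0:
        return volume, AnnotationSet([])
    if not vessel_mask.any():
        raise ValueError("cannot implant aneurysms: vessel mask is empty")

    spacing = volume.spacing
    shape = np.asarray(volume.shape)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0xA4E0]))

    wall = vessel_mask & ~ndimage.binary_erosion(vessel_mask)
    wall_idx = np.argwhere(wall)
    smooth = ndimage.gaussian_filter(vessel_mask.astype(np.float32), 2.0)
    grad = np.stack(np.gradient(smooth), axis=-1)

    data = np.array(volume.data, dtype=np.float32, copy=True)
    signal = np.array(volume.meta.get("signal", data), dtype=np.float32, copy=True)
    taken = np.zeros(volume.shape, dtype=bool)
    regions: list[Annotation] = []
    grids = np.indices(volume.shape, dtype=np.float32)

    offset_vox = 0.5 * sum(config.vessel_radius_range_mm) / spacing  # nominal vessel radius
    for ann_id in range(1, config.n_aneurysms + 1):
        placed = False
        for _ in range(300):
            w = wall_idx[rng.integers(len(wall_idx))]
            normal = -grad[tuple(w)]
            if np.linalg.norm(normal) < 1e-8:
                continue
            normal = _unit(normal)
            d_mm = rng.uniform(*config.aneurysm_diameter_range_mm)
            r_vox = 0.5 * d_mm / spacing
            center = w + normal * offset_vox
            if np.any(center - r_vox < 0) or np.any(center + r_vox > shape - 1):
                continue
            dist2 = sum((grids[a] - center[a]) ** 2 for a in range(3))
            sphere = dist2 <= r_vox**2
            if not sphere.any() or (sphere & taken).any():
                continue
            data[sphere] = config.vessel_intensity + (
                rng.normal(0.0, config.noise_sigma, size=int(sphere.sum()))
                if config.noise_sigma > 0 else 0.0
            )
            signal[sphere] = config.vessel_intensity
            taken |= sphere
            centroid = tuple(float(c) for c in np.argwhere(sphere).mean(axis=0))
            regions.append(
                Annotation(
                    id=ann_id,
                    mask=sphere,
                    centroid_ijk=centroid,
                    equivalent_diameter_mm=equivalent_diameter_mm(sphere, spacing),
                    location_label=_location_label(center, volume.meta, spacing),
                )
            )
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place aneurysm {ann_id}: volume too crowded or too small "
                f"for diameters in {config.aneurysm_diameter_range_mm} mm"
            )

    meta = dict(volume.meta)
    meta["signal"] = signal
    out = Volume(data, spacing, meta)
    annset = AnnotationSet(regions)
    annset.validate(spacing)
    return out, annset


def generate_phantom(config: PhantomConfig) -> tuple[Volume, np.ndarray, AnnotationSet]:
    """One seeded case end to end: vessels, noise, implanted aneurysms."""
    vol, vessel_mask = generate_vessel_volume(config)
    vol, anns = implant_aneurysms(vol, vessel_mask, config)
    return vol, vessel_mask, anns


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def generate_cohort(
    n_volumes: int,
    config: PhantomConfig,
    seed: int,
    out_dir: str | Path | None = None,
) -> tuple[list[tuple[Volume, np.ndarray, AnnotationSet]], dict]:
    """Generate a reproducible multi-case cohort with a JSON manifest.

    Per-case seeds are spawned deterministically from ``seed``; rerunning
    with the same ``(config, seed)`` reproduces every volume, mask and
    manifest byte.  When ``out_dir`` is given, each case is written as an
    uncompressed NIfTI volume plus an integer aneurysm label mask, and the
    manifest (case ids, per-case seeds, aneurysm table) as ``manifest.json``.
    """
    if n_volumes < 1:
        raise ValueError("n_volumes must be >= 1")
    # derive bounded per-case seeds from the cohort seed
    root = np.random.SeedSequence([int(seed), 0xC0407])
    case_seeds = [int(s) for s in
                  np.random.default_rng(root).integers(0, 2**31 - 1, size=n_volumes)]

    cases = []
    manifest_cases = []
    out_path = None
    if out_dir is not None:
        out_path = Path(out_dir)
        out_path.mkdir(parents=True, exist_ok=True)

    for i, case_seed in enumerate(case_seeds):
        case_id = f"case_{i:03d}"
        cfg = replace(config, seed=case_seed)
        vol, vessel_mask, anns = generate_phantom(cfg)
        cases.append((vol, vessel_mask, anns))
        entry = {"case_id": case_id, "seed": case_seed, "aneurysms": anns.to_table()}
        if out_path is not None:
            vol_file = out_path / f"{case_id}.nii"
            mask_file = out_path / f"{case_id}_aneurysms.nii"
            vol.save(vol_file)
            labels = anns.label_volume() if len(anns) else np.zeros(vol.shape, dtype=np.int16)
            Volume(labels, vol.spacing).save(mask_file)
            entry["volume_file"] = vol_file.name
            entry["mask_file"] = mask_file.name
            entry["volume_sha256"] = _sha256(vol_file)
            entry["mask_sha256"] = _sha256(mask_file)
        manifest_cases.append(entry)

    manifest = {
        "seed": int(seed),
        "n_volumes": int(n_volumes),
        "config": asdict(config),
        "cases": manifest_cases,
    }
    if out_path is not None:
        (out_path / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return cases, manifest
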
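"""Synthetic CT calcium-score phantoms with analytic ground truth.

Lesions are voxelized ellipsoids (or boxes, for exact voxel counts) placed
in a uniform soft-tissue background. Voxelization is by centre-inclusion —
a voxel belongs to a lesion iff its centre lies inside the solid — which
makes the per-lesion voxel count, volume, HU statistics, per-slice areas,
centroid and hence Agatston/mass scores exactly computable in closed form
from the voxel set before noise is added. Territory labels cover each
lesion plus a small dilated neighborhood, emulating an analyst's mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from calciomics.volumes import CTVolume, TerritoryMask, TERRITORY_CODES, write_volume, write_mask
from calciomics.features import agatston_weight, MASS_CALIBRATION_DEFAULT

_NAME_TO_CODE = {v: k for k, v in TERRITORY_CODES.items()}


@dataclass(frozen=True)
class LesionSpec:
    """One synthetic calcification.

    ``center_mm`` is (x, y, z) in local volume coordinates (z measured from
    the top slice); ``radii_mm`` are ellipsoid semi-axes (or box half-extents
    when ``shape='box'``). The HU profile is uniform at ``peak_hu`` or falls
    linearly from the peak at the centre to 130 at the boundary.
    """

    territory: str
    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    peak_hu: float = 300.0
    profile: str = "uniform"
    shape: str = "ellipsoid"


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, lesion list and noise model of a synthetic phantom."""

    shape: tuple[int, int, int] = (40, 128, 128)
    spacing: tuple[float, float, float] = (0.5, 0.5, 2.5)  # (dx, dy, dz) mm
    lesions: tuple = ()
    background_hu: float = 40.0
    noise_sd: float = 0.0
    seed: int = 0
    territory_dilation_vox: int = 1


def _lesion_voxels(spec: LesionSpec, shape, spacing) -> tuple[np.ndarray, np.ndarray]:
    """Voxel indices (n,3) and pre-noise HU values of one lesion."""
    dx, dy, dz = spacing
    cx, cy, cz = spec.center_mm
    rx, ry, rz = spec.radii_mm
    # bounding index ranges
    i0 = max(0, int(np.floor((cz - rz) / dz)))
    i1 = min(shape[0] - 1, int(np.ceil((cz + rz) / dz)))
    j0 = max(0, int(np.floor((cy - ry) / dy)))
    j1 = min(shape[1] - 1, int(np.ceil((cy + ry) / dy)))
    k0 = max(0, int(np.floor((cx - rx) / dx)))
    k1 = min(shape[2] - 1, int(np.ceil((cx + rx) / dx)))
    ii, jj, kk = np.meshgrid(np.arange(i0, i1 + 1), np.arange(j0, j1 + 1),
                             np.arange(k0, k1 + 1), indexing="ij")
    x, y, z = kk * dx, jj * dy, ii * dz
    if spec.shape == "box":
        inside = (np.abs(x - cx) <= rx) & (np.abs(y - cy) <= ry) & (np.abs(z - cz) <= rz)
        rho = np.zeros_like(x)
    elif spec.shape == "ellipsoid":
        rho = np.sqrt(((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2)
        inside = rho <= 1.0
    else:
        raise ValueError(f"unknown lesion shape {spec.shape!r}")
    idx = np.column_stack([ii[inside], jj[inside], kk[inside]])
    if spec.profile == "uniform":
        hu = np.full(len(idx), float(spec.peak_hu))
    elif spec.profile == "linear-falloff":
        hu = 130.0 + (spec.peak_hu - 130.0) * (1.0 - rho[inside])
    else:
        raise ValueError(f"unknown HU profile {spec.profile!r}")
    return idx, hu


def _lesion_truth(idx: np.ndarray, hu: np.ndarray, spacing) -> dict:
    dx, dy, dz = spacing
    w = hu / hu.sum()
    per_slice = []
    agatston = 0.0
    for sl in np.unique(idx[:, 0]):
        m = idx[:, 0] == sl
        area = float(m.sum()) * dx * dy
        mx = float(hu[m].max())
        per_slice.append((int(sl), area, mx))
        agatston += area * agatston_weight(mx)
    volume = float(len(idx)) * dx * dy * dz
    mean_hu = float(hu.mean())
    return {
        "n_voxels": int(len(idx)),
        "volume_mm3": volume,
        "mean_hu": mean_hu,
        "max_hu": float(hu.max()),
        "centroid_mm": (float(np.sum(w * idx[:, 2]) * dx),
                        float(np.sum(w * idx[:, 1]) * dy),
                        float(np.sum(w * idx[:, 0]) * dz)),
        "per_slice_areas": per_slice,
        "agatston": float(agatston),
        "mass_mg": float(MASS_CALIBRATION_DEFAULT * mean_hu * volume),
    }


def make_phantom(spec: PhantomSpec) -> tuple[CTVolume, TerritoryMask, dict]:
    """Voxelize a phantom spec into (volume, mask, ground truth).

    Ground truth lists each lesion's pre-noise measurements under this
    package's scoring definitions, plus whole-heart totals. Lesions of
    different territories whose voxel sets overlap are a spec error.
    """
    data = np.full(spec.shape, float(spec.background_hu))
    labels = np.zeros(spec.shape, dtype=np.int32)
    owner = np.zeros(spec.shape, dtype=np.int32)  # which lesion claimed a voxel
    truth_lesions = []
    for li, lspec in enumerate(spec.lesions, start=1):
        if lspec.territory not in _NAME_TO_CODE or lspec.territory == "BG":
            raise ValueError(f"unknown territory {lspec.territory!r}")
        idx, hu = _lesion_voxels(lspec, spec.shape, spec.spacing)
        if len(idx) == 0:
            raise ValueError(f"lesion {li} voxelizes to nothing (too small for the grid)")
        prev = owner[idx[:, 0], idx[:, 1], idx[:, 2]]
        if np.any(prev != 0):
            other = int(prev[prev != 0][0])
            if spec.lesions[other - 1].territory != lspec.territory:
                raise ValueError(
                    f"lesions {other} and {li} of different territories overlap")
            raise ValueError(f"lesions {other} and {li} overlap")
        data[idx[:, 0], idx[:, 1], idx[:, 2]] = hu
        owner[idx[:, 0], idx[:, 1], idx[:, 2]] = li
        lesion_mask = np.zeros(spec.shape, dtype=bool)
        lesion_mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        if spec.territory_dilation_vox > 0:
            lesion_mask = ndimage.binary_dilation(
                lesion_mask, structure=np.ones((3, 3, 3), dtype=bool),
                iterations=spec.territory_dilation_vox)
        code = _NAME_TO_CODE[lspec.territory]
        labels[lesion_mask & (labels == 0)] = code
        t = _lesion_truth(idx, hu, spec.spacing)
        t["territory"] = lspec.territory
        truth_lesions.append(t)

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sd, size=spec.shape)

    truth = {
        "lesions": truth_lesions,
        "total_agatston": float(sum(t["agatston"] for t in truth_lesions)),
        "total_mass_mg": float(sum(t["mass_mg"] for t in truth_lesions)),
        "total_volume_mm3": float(sum(t["volume_mm3"] for t in truth_lesions)),
        "num_lesions": len(truth_lesions),
    }
    vol = CTVolume(data=data, spacing=spec.spacing)
    mask = TerritoryMask(labels=labels)
    return vol, mask, truth


__all__ = ["LesionSpec", "PhantomSpec", "make_phantom", "write_volume", "write_mask"]
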
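"""Calcified lesion detection from a CT volume plus territory mask.

A calcification is a 3D connected component of voxels with HU >= 130 that
lie inside a coronary territory, containing at least three voxels — the
standard calcium-scoring detection rule. Connectivity defaults to
26-neighborhood in 3D (configurable to 6) because 2.5 mm slices make
through-plane adjacency meaningful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from calciomics.volumes import CTVolume, TerritoryMask, TERRITORY_CODES, validate_pair

logger = logging.getLogger(__name__)

#: Detection defaults: minimum HU and minimum connected voxel count.
HU_MIN_DEFAULT = 130.0
MIN_VOXELS_DEFAULT = 3


@dataclass(frozen=True)
class Lesion:
    """One detected calcification and its elemental measurements."""

    lesion_id: int
    territory: str
    voxel_indices: np.ndarray          # (n, 3) array of (i, j, k)
    hu_values: np.ndarray              # (n,) HU per voxel
    volume_mm3: float
    centroid_mm: tuple[float, float, float]   # HU-weighted sub-voxel (x, y, z)
    per_slice_areas: tuple              # ((slice index, area mm2, slice max HU), ...)

    @property
    def n_voxels(self) -> int:
        return len(self.hu_values)

    @property
    def max_hu(self) -> float:
        return float(self.hu_values.max())

    @property
    def mean_hu(self) -> float:
        return float(self.hu_values.mean())

    @property
    def dist_to_top_mm(self) -> float:
        """Centroid z-distance from the top (superior-most) slice plane."""
        return float(self.centroid_mm[2])


@dataclass
class LesionTable:
    """Ordered collection of lesions with provenance.

    Lesions are ordered by territory code, then by centroid z (superior
    first), with ties broken on (y, x) — the deterministic "consecutive
    sequential order" used by the sequential distance features.
    """

    lesions: list[Lesion]
    spacing: tuple[float, float, float]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.lesions)

    def by_territory(self, territory: str) -> list[Lesion]:
        return [l for l in self.lesions if l.territory == territory]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for l in self.lesions:
            rows.append({
                "lesion_id": l.lesion_id,
                "territory": l.territory,
                "n_voxels": l.n_voxels,
                "volume_mm3": l.volume_mm3,
                "max_hu": l.max_hu,
                "mean_hu": l.mean_hu,
                "centroid_x_mm": l.centroid_mm[0],
                "centroid_y_mm": l.centroid_mm[1],
                "centroid_z_mm": l.centroid_mm[2],
            })
        return pd.DataFrame(rows, columns=[
            "lesion_id", "territory", "n_voxels", "volume_mm3", "max_hu",
            "mean_hu", "centroid_x_mm", "centroid_y_mm", "centroid_z_mm"])


def threshold_candidates(vol: CTVolume, mask: TerritoryMask, hu_min: float = HU_MIN_DEFAULT) -> np.ndarray:
    """Binary candidate map: HU >= hu_min (inclusive) AND inside a territory."""
    validate_pair(vol, mask)
    return (vol.data >= hu_min) & (mask.labels != 0)


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")


def extract_lesions(
    vol: CTVolume,
    mask: TerritoryMask,
    hu_min: float = HU_MIN_DEFAULT,
    min_voxels: int = MIN_VOXELS_DEFAULT,
    connectivity: int = 26,
) -> LesionTable:
    """Detect calcifications and return them as a LesionTable.

    Connected components of the candidate map with at least ``min_voxels``
    voxels become lesions; smaller components are discarded. A component's
    territory is the majority mask label over its voxels; an exact tie is
    broken toward the lowest territory code with a logged warning.
    """
    validate_pair(vol, mask)
    candidates = threshold_candidates(vol, mask, hu_min)
    labeled, n_comp = ndimage.label(candidates, structure=_connectivity_structure(connectivity))
    dx, dy, dz = vol.spacing
    voxel_vol = dx * dy * dz

    raw = []
    for comp in range(1, n_comp + 1):
        idx = np.argwhere(labeled == comp)
        if len(idx) < min_voxels:
            continue
        hu = vol.data[idx[:, 0], idx[:, 1], idx[:, 2]]
        terr_codes = mask.labels[idx[:, 0], idx[:, 1], idx[:, 2]]
        codes, counts = np.unique(terr_codes, return_counts=True)
        winners = codes[counts == counts.max()]
        if len(winners) > 1:
            logger.warning(
                "lesion spans territories %s with tied voxel counts; assigning lowest code %d",
                winners.tolist(), winners.min())
        territory = mask.code_map[int(winners.min())]
        # HU-weighted sub-voxel centroid in local mm coordinates
        w = hu / hu.sum()
        cx = float(np.sum(w * idx[:, 2]) * dx)
        cy = float(np.sum(w * idx[:, 1]) * dy)
        cz = float(np.sum(w * idx[:, 0]) * dz)
        per_slice = []
        for sl in np.unique(idx[:, 0]):
            in_slice = idx[:, 0] == sl
            per_slice.append((int(sl), float(in_slice.sum() * dx * dy), float(hu[in_slice].max())))
        raw.append(Lesion(
            lesion_id=-1, territory=territory, voxel_indices=idx, hu_values=hu,
            volume_mm3=float(len(idx) * voxel_vol), centroid_mm=(cx, cy, cz),
            per_slice_areas=tuple(per_slice)))

    code_of = {v: k for k, v in mask.code_map.items()}
    raw.sort(key=lambda l: (code_of[l.territory], l.centroid_mm[2], l.centroid_mm[1], l.centroid_mm[0]))
    lesions = [
        Lesion(lesion_id=i + 1, territory=l.territory, voxel_indices=l.voxel_indices,
               hu_values=l.hu_values, volume_mm3=l.volume_mm3, centroid_mm=l.centroid_mm,
               per_slice_areas=l.per_slice_areas)
        for i, l in enumerate(raw)
    ]
    prov = {"hu_min": hu_min, "min_voxels": min_voxels, "connectivity": connectivity,
            "spacing": vol.spacing, "shape": vol.shape}
    return LesionTable(lesions=lesions, spacing=vol.spacing, provenance=prov)


def count_summary(table: LesionTable, hu_dense_threshold: float = 1000.0, dense_strict: bool = True) -> dict:
    """Whole-heart lesion counts and flags.

    ``is_humax_above_1000`` uses a strict ``>`` comparison by default (the
    "dense calcification" flag); set ``dense_strict=False`` for ``>=``.
    """
    per_territory = {t: 0 for t in ("LM", "LAD", "LCX", "RCA")}
    max_hu = 0.0
    for l in table.lesions:
        per_territory[l.territory] = per_territory.get(l.territory, 0) + 1
        max_hu = max(max_hu, l.max_hu)
    n_calcified = sum(1 for v in per_territory.values() if v > 0)
    if dense_strict:
        dense = max_hu > hu_dense_threshold
    else:
        dense = max_hu >= hu_dense_threshold
    return {
        "num_lesions_total": len(table),
        "num_lesions_per_territory": per_territory,
        "num_calcified_arteries": n_calcified,
        "is_calcified_arteries_ge2": n_calcified >= 2,
        "max_hu_heart": max_hu if table.lesions else 0.0,
        "is_humax_above_1000": bool(dense) if table.lesions else False,
    }


def write_lesion_csv(table: LesionTable, path: str) -> str:
    """LesionTable as CSV with a JSON provenance header comment line."""
    import json as _json
    with open(path, "w") as fh:
        fh.write("# provenance: " + _json.dumps(table.provenance, default=str) + "\n")
        table.to_frame().to_csv(fh, index=False)
    return path
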
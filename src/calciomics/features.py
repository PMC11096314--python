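"""Calcium-omics feature hierarchy.

Features are computed at three levels and assembled into a fixed 80-entry
vector per patient:

* per-lesion elemental features — Agatston, mass, volume, HU moments,
  shape (sphericity, elongation), distance to the next lesion, distance to
  the top of the CT volume;
* per-territory aggregates for LM / LAD / LCX / RCA — score sums, lesion
  counts, diffusivity (lesions per mm of calcified arterial path),
  sequential centroid distances, HU statistics;
* whole-heart aggregates and lesion-level statistics (e.g. the maximum
  first moment over lesions, skewness of per-lesion masses).

The exact composition of the 80-entry vector is pinned by a versioned
registry manifest so model inputs are stable across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from calciomics.lesions import Lesion, LesionTable
from calciomics.volumes import TERRITORY_NAMES

#: HU histogram bin edges (half-open bins, last bin unbounded).
HU_HIST_EDGES = (130.0, 200.0, 300.0, 400.0, 1000.0, np.inf)

#: Default mass-score calibration, mg per (HU * mm^3).
MASS_CALIBRATION_DEFAULT = 0.001


# ---------------------------------------------------------------------------
# Elemental (per-lesion) features
# ---------------------------------------------------------------------------

def agatston_weight(slice_max_hu: float) -> int:
    """Density weight for one axial slice of a lesion.

    Standard bins: 130-199 HU -> 1, 200-299 -> 2, 300-399 -> 3, >= 400 -> 4.
    """
    if slice_max_hu < 130:
        raise ValueError(f"Agatston weight undefined below 130 HU (got {slice_max_hu})")
    if slice_max_hu < 200:
        return 1
    if slice_max_hu < 300:
        return 2
    if slice_max_hu < 400:
        return 3
    return 4


def lesion_agatston(lesion: Lesion) -> float:
    """Agatston score of one lesion: per-slice area x density weight, summed."""
    return float(sum(area * agatston_weight(mx) for _, area, mx in lesion.per_slice_areas))


def lesion_mass(lesion: Lesion, calibration_c: float = MASS_CALIBRATION_DEFAULT) -> float:
    """Mass score in mg: calibration x mean HU x volume."""
    return float(calibration_c * lesion.mean_hu * lesion.volume_mm3)


def _voxel_surface_area(idx: np.ndarray, spacing) -> float:
    """Surface area of a voxelized lesion: exposed faces x face areas."""
    dx, dy, dz = spacing
    face_area = {0: dx * dy, 1: dx * dz, 2: dy * dz}   # faces normal to z, y, x
    lo = idx.min(axis=0)
    shape = idx.max(axis=0) - lo + 3
    grid = np.zeros(shape, dtype=bool)
    g = idx - lo + 1
    grid[g[:, 0], g[:, 1], g[:, 2]] = True
    area = 0.0
    for axis in range(3):
        for shift in (1, -1):
            neighbor = np.roll(grid, shift, axis=axis)
            area += np.count_nonzero(grid & ~neighbor) * face_area[axis]
    return float(area)


def lesion_shape(lesion: Lesion, spacing) -> tuple[float, float]:
    """Sphericity and elongation of a lesion.

    Sphericity = pi^(1/3) (6V)^(2/3) / A with A the voxelized surface area;
    it approaches 1 only in the continuum-sphere limit. Elongation =
    sqrt(lambda1 / lambda3) from the covariance of voxel mm coordinates,
    with lambda3 floored at (min spacing / 2)^2 so planar and collinear
    lesions stay finite.
    """
    dx, dy, dz = spacing
    idx = lesion.voxel_indices
    V = lesion.volume_mm3
    A = _voxel_surface_area(idx, spacing)
    sphericity = float(np.pi ** (1.0 / 3.0) * (6.0 * V) ** (2.0 / 3.0) / A)
    coords = np.column_stack([idx[:, 2] * dx, idx[:, 1] * dy, idx[:, 0] * dz])
    cov = np.cov(coords.T, bias=True)
    eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    floor = (min(spacing) / 2.0) ** 2
    lam1 = max(eigvals[0], floor)
    lam3 = max(eigvals[2], floor)
    elongation = float(np.sqrt(lam1 / lam3))
    return sphericity, elongation


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def hu_statistics(values) -> tuple[float, float, float, float]:
    """Population mean, sd, skewness (m3/m2^1.5) and excess kurtosis.

    Conventions: skewness needs n >= 3 and kurtosis n >= 4, otherwise 0;
    a constant sample has sd = skewness = kurtosis = 0.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("hu_statistics requires a non-empty sample")
    mean = float(v.mean())
    m2 = float(((v - mean) ** 2).mean())
    sd = float(np.sqrt(m2))
    if m2 == 0.0:
        return mean, 0.0, 0.0, 0.0
    skew = float(((v - mean) ** 3).mean() / m2 ** 1.5) if v.size >= 3 else 0.0
    kurt = float(((v - mean) ** 4).mean() / m2 ** 2 - 3.0) if v.size >= 4 else 0.0
    return mean, sd, skew, kurt


def hu_histogram(values, edges=HU_HIST_EDGES) -> np.ndarray:
    """Counts in half-open HU bins [e_k, e_{k+1}); sums to len(values)."""
    v = np.asarray(values, dtype=float)
    if v.size and v.min() < edges[0]:
        raise ValueError(f"HU value below first bin edge {edges[0]}")
    counts = np.zeros(len(edges) - 1, dtype=int)
    for i in range(len(edges) - 1):
        counts[i] = int(np.count_nonzero((v >= edges[i]) & (v < edges[i + 1])))
    return counts


# ---------------------------------------------------------------------------
# Sequential distance features
# ---------------------------------------------------------------------------

def sequential_distances(lesions: list[Lesion], top_convention: str = "offset"):
    """Sequential centroid distances for an ordered lesion list.

    Returns ``(dist_to_next, dist_first2last_mm, dist_top2last_mm)`` where
    ``dist_to_next[i]`` is the Euclidean centroid gap from lesion i to i+1
    (None for the last lesion), ``dist_first2last_mm`` sums consecutive gaps
    along the sequence, and ``dist_top2last_mm`` measures from the top of
    the volume to the last lesion. With the default ``offset`` convention
    the top reference point is the first lesion's centroid projected onto
    the slice-0 plane (same x, y; z = 0); the ``z`` convention uses the
    last lesion's centroid z only.
    """
    n = len(lesions)
    if n == 0:
        return [], 0.0, 0.0
    cents = np.array([l.centroid_mm for l in lesions], dtype=float)
    gaps = np.linalg.norm(np.diff(cents, axis=0), axis=1) if n > 1 else np.array([])
    dist_to_next = [float(g) for g in gaps] + [None]
    dist_first2last = float(gaps.sum())
    if top_convention == "offset":
        top_point = np.array([cents[0, 0], cents[0, 1], 0.0])
        dist_top2last = float(np.linalg.norm(cents[-1] - top_point))
    elif top_convention == "z":
        dist_top2last = float(cents[-1, 2])
    else:
        raise ValueError(f"unknown top_convention {top_convention!r}")
    return dist_to_next, dist_first2last, dist_top2last


def territory_diffusivity(num_lesions: int, dist_first2last_mm: float) -> float:
    """Lesions per mm of calcified arterial path within one territory.

    Boundary conventions: an empty territory has diffusivity 0 and a
    single-lesion territory has diffusivity 1; otherwise the ratio of the
    lesion count to the first-to-last sequential centroid distance.
    """
    if dist_first2last_mm < 0:
        raise ValueError("distance must be non-negative")
    if num_lesions == 0:
        return 0.0
    if num_lesions == 1:
        return 1.0
    if dist_first2last_mm == 0.0:
        raise ValueError("degenerate geometry: >= 2 lesions with zero path length")
    return float(num_lesions) / float(dist_first2last_mm)


# ---------------------------------------------------------------------------
# Registry and the 80-entry vector
# ---------------------------------------------------------------------------

_WHOLE_HEART = [
    "Agatston", "MassScore", "VolumeScore", "NumLesions",
    "NumCalcifiedArteries", "Is_CalcifiedArteries_ge2",
    "HUmax", "Is_HUmaxAbove1000", "HUmean",
    "HUhist_130_200", "HUhist_200_300", "HUhist_300_400",
    "HUhist_400_1000", "HUhist_1000plus",
]

_TERRITORIAL = [
    "Agatston", "Mass", "Volume", "NumLesions", "Diffusivity",
    "DistFirst2LastLesionPerArtery", "DistTop2LastLesion",
    "HUmax", "HUmean", "HUsd", "HUskewness", "HUkurtosis",
    "MeanDistToNextLesion",
]

_LESION_AGG = [
    "MaxLesionFirstMoment", "MeanLesionFirstMoment", "MaxLesionSecondMoment",
    "MeanLesionMass", "MaxLesionMass", "SkewnessLesionMass", "KurtosisLesionMass",
    "MeanLesionVolume", "MaxLesionVolume", "MaxLesionAgatston",
    "MeanLesionSphericity", "MinLesionSphericity",
    "MeanLesionElongation", "MaxLesionElongation",
]


@dataclass(frozen=True)
class FeatureRegistry:
    """Versioned manifest fixing the names and order of the feature vector."""

    version: str
    names: tuple

    def __len__(self) -> int:
        return len(self.names)

    def to_json(self, path: str) -> str:
        with open(path, "w") as fh:
            json.dump({"version": self.version, "names": list(self.names)}, fh, indent=1)
        return path

    @classmethod
    def from_json(cls, path: str) -> "FeatureRegistry":
        with open(path) as fh:
            d = json.load(fh)
        return cls(version=d["version"], names=tuple(d["names"]))


def default_registry() -> FeatureRegistry:
    """The standard 80-feature manifest.

    14 whole-heart features, 13 features per territory (LM, LAD, LCX, RCA)
    named ``<Feature>_<Territory>``, and 14 lesion-aggregate statistics.
    """
    names = list(_WHOLE_HEART)
    for t in TERRITORY_NAMES:
        names += [f"{f}_{t}" for f in _TERRITORIAL]
    names += list(_LESION_AGG)
    assert len(names) == 80
    return FeatureRegistry(version="1.0", names=tuple(names))


def territory_features(
    table: LesionTable,
    territory: str,
    calibration_c: float = MASS_CALIBRATION_DEFAULT,
    diffusivity_denominator: str = "path",
    top_convention: str = "offset",
) -> dict:
    """All per-territory aggregates for one territory (zeros when empty).

    ``diffusivity_denominator`` selects the summed sequential centroid path
    (default, identical to DistFirst2LastLesionPerArtery) or the straight
    ``chord`` from first to last centroid.
    """
    lesions = table.by_territory(territory)
    out = {f: 0.0 for f in _TERRITORIAL}
    if not lesions:
        out["Diffusivity"] = territory_diffusivity(0, 0.0)
        return out
    dist_to_next, d_f2l, d_t2l = sequential_distances(lesions, top_convention=top_convention)
    hu = np.concatenate([l.hu_values for l in lesions])
    mean, sd, skew, kurt = hu_statistics(hu)
    out.update({
        "Agatston": sum(lesion_agatston(l) for l in lesions),
        "Mass": sum(lesion_mass(l, calibration_c) for l in lesions),
        "Volume": sum(l.volume_mm3 for l in lesions),
        "NumLesions": float(len(lesions)),
        "DistFirst2LastLesionPerArtery": d_f2l,
        "DistTop2LastLesion": d_t2l,
        "HUmax": float(hu.max()), "HUmean": mean, "HUsd": sd,
        "HUskewness": skew, "HUkurtosis": kurt,
        "MeanDistToNextLesion": float(np.mean([d for d in dist_to_next if d is not None]))
        if len(lesions) > 1 else 0.0,
    })
    if len(lesions) == 1:
        out["Diffusivity"] = territory_diffusivity(1, 0.0)
    else:
        if diffusivity_denominator == "path":
            denom = d_f2l
        elif diffusivity_denominator == "chord":
            denom = float(np.linalg.norm(
                np.asarray(lesions[-1].centroid_mm) - np.asarray(lesions[0].centroid_mm)))
        else:
            raise ValueError(f"unknown diffusivity denominator {diffusivity_denominator!r}")
        out["Diffusivity"] = territory_diffusivity(len(lesions), denom)
    return out


def build_feature_vector(
    table: LesionTable,
    registry: FeatureRegistry | None = None,
    calibration_c: float = MASS_CALIBRATION_DEFAULT,
    diffusivity_denominator: str = "path",
    top_convention: str = "offset",
    dense_strict: bool = True,
) -> dict:
    """Assemble the full calcium-omics vector for one patient.

    Every registry entry is populated; a patient with no detected calcium
    (a common, valid case) yields an all-zero vector with false flags.
    Raises a schema error if the computed names do not cover the registry.
    """
    from calciomics.lesions import count_summary

    registry = registry or default_registry()
    values: dict[str, float] = {}

    summary = count_summary(table, dense_strict=dense_strict)
    lesions = table.lesions
    hu_all = np.concatenate([l.hu_values for l in lesions]) if lesions else np.array([])
    hist = hu_histogram(hu_all) if hu_all.size else np.zeros(5, dtype=int)
    values.update({
        "Agatston": sum(lesion_agatston(l) for l in lesions),
        "MassScore": sum(lesion_mass(l, calibration_c) for l in lesions),
        "VolumeScore": sum(l.volume_mm3 for l in lesions),
        "NumLesions": float(summary["num_lesions_total"]),
        "NumCalcifiedArteries": float(summary["num_calcified_arteries"]),
        "Is_CalcifiedArteries_ge2": float(summary["is_calcified_arteries_ge2"]),
        "HUmax": summary["max_hu_heart"],
        "Is_HUmaxAbove1000": float(summary["is_humax_above_1000"]),
        "HUmean": float(hu_all.mean()) if hu_all.size else 0.0,
        "HUhist_130_200": float(hist[0]), "HUhist_200_300": float(hist[1]),
        "HUhist_300_400": float(hist[2]), "HUhist_400_1000": float(hist[3]),
        "HUhist_1000plus": float(hist[4]),
    })

    for t in TERRITORY_NAMES:
        tf = territory_features(table, t, calibration_c, diffusivity_denominator, top_convention)
        for f in _TERRITORIAL:
            values[f"{f}_{t}"] = float(tf[f])

    if lesions:
        first_moments = np.array([l.mean_hu for l in lesions])
        second_moments = np.array([float(np.var(l.hu_values)) for l in lesions])
        masses = np.array([lesion_mass(l, calibration_c) for l in lesions])
        vols = np.array([l.volume_mm3 for l in lesions])
        agats = np.array([lesion_agatston(l) for l in lesions])
        shapes = np.array([lesion_shape(l, table.spacing) for l in lesions])
        _, _, mass_skew, mass_kurt = hu_statistics(masses)
        values.update({
            "MaxLesionFirstMoment": float(first_moments.max()),
            "MeanLesionFirstMoment": float(first_moments.mean()),
            "MaxLesionSecondMoment": float(second_moments.max()),
            "MeanLesionMass": float(masses.mean()),
            "MaxLesionMass": float(masses.max()),
            "SkewnessLesionMass": mass_skew,
            "KurtosisLesionMass": mass_kurt,
            "MeanLesionVolume": float(vols.mean()),
            "MaxLesionVolume": float(vols.max()),
            "MaxLesionAgatston": float(agats.max()),
            "MeanLesionSphericity": float(shapes[:, 0].mean()),
            "MinLesionSphericity": float(shapes[:, 0].min()),
            "MeanLesionElongation": float(shapes[:, 1].mean()),
            "MaxLesionElongation": float(shapes[:, 1].max()),
        })
    else:
        for f in _LESION_AGG:
            values[f] = 0.0

    missing = [n for n in registry.names if n not in values]
    if missing:
        raise KeyError(f"registry features not computed: {missing}")
    vec = {name: float(values[name]) for name in registry.names}
    if any(not np.isfinite(v) for v in vec.values()):
        bad = [n for n, v in vec.items() if not np.isfinite(v)]
        raise ValueError(f"non-finite feature values: {bad}")
    return vec
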
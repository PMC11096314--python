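"""Simulated survival cohorts with known generative hazards.

Patients receive feature vectors drawn from configurable distributions; a
linear predictor eta = beta . x drives a Weibull proportional-hazards event
time; censoring combines an administrative cap (6 years = 2192 days,
matching typical calcium-score follow-up programs) with exponential
dropout. The generative coefficients, baseline and censoring realization
are returned so model-fitting code can be checked by parameter recovery.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ADMIN_CENSOR_DAYS = 2192  # 6-year administrative cap


@dataclass(frozen=True)
class CohortSpec:
    """Generative description of a simulated cohort.

    ``beta`` maps feature names to log-hazard coefficients; features not in
    ``feature_dists`` default to standard normal draws. ``weibull_scale``
    is in days; when None it is calibrated so the realized event fraction
    hits ``target_event_fraction``. ``dropout_mean_days`` sets exponential
    dropout (None disables it, leaving administrative censoring only).
    """

    n: int = 1000
    beta: dict = field(default_factory=dict)
    feature_dists: dict = field(default_factory=dict)
    n_noise_features: int = 0
    weibull_shape: float = 1.2
    weibull_scale: float | None = None
    target_event_fraction: float | None = 0.14
    dropout_mean_days: float | None = 2500.0
    seed: int = 0

    def feature_names(self) -> list:
        names = list(self.beta)
        for n in self.feature_dists:
            if n not in names:
                names.append(n)
        names += [f"noise_{i}" for i in range(self.n_noise_features)]
        return names


def _draw_feature(rng, dist, n):
    kind = dist[0]
    if kind == "normal":
        return rng.normal(dist[1], dist[2], n)
    if kind == "lognormal":
        return rng.lognormal(dist[1], dist[2], n)
    if kind == "poisson":
        return rng.poisson(dist[1], n).astype(float)
    if kind == "bernoulli":
        return (rng.uniform(size=n) < dist[1]).astype(float)
    if kind == "uniform":
        return rng.uniform(dist[1], dist[2], n)
    raise ValueError(f"unknown feature distribution {kind!r}")


def simulate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Draw (features, survival records, generative truth) for one cohort.

    Event times follow T = scale * (E / exp(eta))^(1/shape) with E ~ Exp(1),
    i.e. a Weibull baseline under proportional hazards. Observed times are
    rounded to whole days with a floor of 1 day.
    """
    rng = np.random.default_rng(spec.seed)
    names = spec.feature_names()
    X = pd.DataFrame({
        name: _draw_feature(rng, spec.feature_dists.get(name, ("normal", 0.0, 1.0)), spec.n)
        for name in names
    })
    X.insert(0, "patient_id", [f"P{idx:05d}" for idx in range(spec.n)])

    eta = np.zeros(spec.n)
    for name, b in spec.beta.items():
        eta += b * X[name].to_numpy()
    eta = eta - eta.mean()  # centre so the scale parameter sets the base rate

    E = rng.exponential(1.0, spec.n)
    if spec.dropout_mean_days is not None:
        dropout = rng.exponential(spec.dropout_mean_days, spec.n)
    else:
        dropout = np.full(spec.n, np.inf)
    censor = np.minimum(dropout, ADMIN_CENSOR_DAYS)

    def _event_fraction(scale):
        T = scale * (E / np.exp(eta)) ** (1.0 / spec.weibull_shape)
        return float((T <= censor).mean())

    if spec.weibull_scale is None:
        if spec.target_event_fraction is None:
            raise ValueError("need weibull_scale or target_event_fraction")
        f = spec.target_event_fraction
        lo, hi = 1.0, 1e8
        f_lo, f_hi = _event_fraction(lo), _event_fraction(hi)
        if not (f_hi <= f <= f_lo):
            raise ValueError(
                f"target event fraction {f} outside achievable range [{f_hi:.3f}, {f_lo:.3f}]")
        for _ in range(80):
            mid = np.sqrt(lo * hi)
            if _event_fraction(mid) > f:
                lo = mid
            else:
                hi = mid
        scale = float(np.sqrt(lo * hi))
    else:
        scale = float(spec.weibull_scale)

    T = scale * (E / np.exp(eta)) ** (1.0 / spec.weibull_shape)
    event = (T <= censor).astype(int)
    time = np.minimum(T, censor)
    time = np.maximum(1, np.round(time)).astype(int)
    time = np.minimum(time, ADMIN_CENSOR_DAYS)

    survival = pd.DataFrame({"patient_id": X["patient_id"], "time_days": time, "event": event})
    truth = {"beta": dict(spec.beta), "weibull_shape": spec.weibull_shape,
             "weibull_scale": scale, "eta": eta, "censor_days": censor,
             "event_fraction": float(event.mean())}
    return X, survival, truth


# ---------------------------------------------------------------------------
# Registry-shaped synthetic cohorts
# ---------------------------------------------------------------------------

def synthetic_feature_cohort(n: int = 2457, seed: int = 0,
                             zero_fraction: float = 0.389,
                             target_event_fraction: float = 0.138,
                             beta: dict | None = None):
    """Simulate a cohort with the full 80-column calcium-omics feature table.

    Emulates the structure of a MACE-enriched calcium-score cohort: about
    39% of patients have zero calcium; the rest draw a log-normal disease
    severity that drives lesion counts (Poisson per territory), mass /
    volume / Agatston scores, HU statistics and the spatial features, with
    the diffusivity 0/1 boundary conventions built in. The hazard acts on
    transformed features (higher mass and lesion count raise risk; dense
    >1000 HU calcification is protective), with a Weibull baseline
    calibrated to the target event fraction under 6-year administrative
    censoring plus exponential dropout.

    Returns ``(features, survival, truth)`` where truth holds the
    generative coefficients and the realized linear predictor.
    """
    from calciomics.features import default_registry

    rng = np.random.default_rng(seed)
    registry = default_registry()
    territories = ("LM", "LAD", "LCX", "RCA")
    if beta is None:
        beta = {  # log-hazard per unit of *transformed* feature
            "ln1p_MassScore": 0.39,
            "ln1p_NumLesions": 0.39,
            "Is_HUmaxAbove1000": -0.34,
            "Diffusivity_LM": 0.5,
        }

    rows = []
    for _ in range(n):
        f = {name: 0.0 for name in registry.names}
        if rng.uniform() >= zero_fraction:
            severity = rng.lognormal(0.0, 1.1)
            terr_w = rng.dirichlet([1.0, 3.0, 2.0, 2.0])  # LAD-dominant disease
            total_hu = []
            for t, w in zip(territories, terr_w):
                n_les = int(rng.poisson(3.0 * severity * w))
                if n_les == 0:
                    continue
                f[f"NumLesions_{t}"] = float(n_les)
                mass = severity * w * rng.lognormal(1.2, 0.5)
                vol = mass / 0.3 * rng.uniform(0.9, 1.1)
                f[f"Mass_{t}"] = mass
                f[f"Volume_{t}"] = vol
                f[f"Agatston_{t}"] = 2.2 * vol * rng.uniform(0.8, 1.2)
                hu_mean = float(np.clip(rng.normal(330.0, 70.0), 140.0, 900.0))
                hu_max = float(min(hu_mean + abs(rng.normal(150.0, 150.0)) * severity ** 0.3, 2500.0))
                f[f"HUmean_{t}"] = hu_mean
                f[f"HUmax_{t}"] = hu_max
                f[f"HUsd_{t}"] = abs(rng.normal(60.0, 20.0))
                f[f"HUskewness_{t}"] = rng.normal(0.8, 0.5)
                f[f"HUkurtosis_{t}"] = rng.normal(0.5, 1.0)
                total_hu.append((hu_mean, hu_max, n_les))
                if n_les == 1:
                    f[f"Diffusivity_{t}"] = 1.0
                    f[f"DistFirst2LastLesionPerArtery_{t}"] = 0.0
                    f[f"DistTop2LastLesion_{t}"] = rng.uniform(20.0, 120.0)
                else:
                    d = rng.uniform(5.0, 15.0) * n_les ** 0.7
                    f[f"DistFirst2LastLesionPerArtery_{t}"] = d
                    f[f"DistTop2LastLesion_{t}"] = d + rng.uniform(10.0, 60.0)
                    f[f"Diffusivity_{t}"] = n_les / d
                    f[f"MeanDistToNextLesion_{t}"] = d / (n_les - 1)
            n_total = sum(f[f"NumLesions_{t}"] for t in territories)
            if n_total > 0:
                f["NumLesions"] = n_total
                f["MassScore"] = sum(f[f"Mass_{t}"] for t in territories)
                f["VolumeScore"] = sum(f[f"Volume_{t}"] for t in territories)
                f["Agatston"] = sum(f[f"Agatston_{t}"] for t in territories)
                calc = [t for t in territories if f[f"NumLesions_{t}"] > 0]
                f["NumCalcifiedArteries"] = float(len(calc))
                f["Is_CalcifiedArteries_ge2"] = float(len(calc) >= 2)
                f["HUmax"] = max(hm for _, hm, _ in total_hu)
                f["Is_HUmaxAbove1000"] = float(f["HUmax"] > 1000.0)
                f["HUmean"] = float(np.average([m for m, _, _ in total_hu],
                                               weights=[k for _, _, k in total_hu]))
                hist = rng.multinomial(int(20 * n_total), [0.35, 0.25, 0.15, 0.2, 0.05])
                for b, name in enumerate(["HUhist_130_200", "HUhist_200_300",
                                          "HUhist_300_400", "HUhist_400_1000",
                                          "HUhist_1000plus"]):
                    f[name] = float(hist[b])
                f["MaxLesionFirstMoment"] = f["HUmean"] * rng.uniform(1.0, 1.4)
                f["MeanLesionFirstMoment"] = f["HUmean"]
                f["MaxLesionSecondMoment"] = f["HUmean"] * rng.uniform(10.0, 40.0)
                f["MeanLesionMass"] = f["MassScore"] / n_total
                f["MaxLesionMass"] = f["MeanLesionMass"] * rng.uniform(1.0, 3.0)
                f["SkewnessLesionMass"] = rng.normal(1.0, 0.5)
                f["KurtosisLesionMass"] = rng.normal(1.0, 1.0)
                f["MeanLesionVolume"] = f["VolumeScore"] / n_total
                f["MaxLesionVolume"] = f["MeanLesionVolume"] * rng.uniform(1.0, 3.0)
                f["MaxLesionAgatston"] = f["Agatston"] / n_total * rng.uniform(1.0, 3.0)
                f["MeanLesionSphericity"] = rng.uniform(0.5, 0.85)
                f["MinLesionSphericity"] = f["MeanLesionSphericity"] * rng.uniform(0.6, 1.0)
                f["MeanLesionElongation"] = rng.uniform(1.2, 3.0)
                f["MaxLesionElongation"] = f["MeanLesionElongation"] * rng.uniform(1.0, 2.0)
        rows.append(f)
    features = pd.DataFrame(rows, columns=list(registry.names))
    features.insert(0, "patient_id", [f"P{idx:05d}" for idx in range(n)])

    eta = np.zeros(n)
    for name, b in beta.items():
        if name.startswith("ln1p_"):
            eta += b * np.log1p(features[name[5:]].to_numpy())
        else:
            eta += b * features[name].to_numpy()
    eta = eta - eta.mean()

    E = rng.exponential(1.0, n)
    dropout = rng.exponential(2500.0, n)
    censor = np.minimum(dropout, ADMIN_CENSOR_DAYS)
    shape = 1.2

    def _event_fraction(scale):
        T = scale * (E / np.exp(eta)) ** (1.0 / shape)
        return float((T <= censor).mean())

    lo, hi = 1.0, 1e8
    for _ in range(80):
        mid = np.sqrt(lo * hi)
        if _event_fraction(mid) > target_event_fraction:
            lo = mid
        else:
            hi = mid
    scale = float(np.sqrt(lo * hi))
    T = scale * (E / np.exp(eta)) ** (1.0 / shape)
    event = (T <= censor).astype(int)
    time = np.minimum(np.maximum(1, np.round(np.minimum(T, censor))).astype(int),
                      ADMIN_CENSOR_DAYS)
    survival = pd.DataFrame({"patient_id": features["patient_id"],
                             "time_days": time, "event": event})
    truth = {"beta": dict(beta), "weibull_shape": shape, "weibull_scale": scale,
             "eta": eta, "event_fraction": float(event.mean())}
    return features, survival, truth


def engineered_screening_cohort(n: int = 600, seed: int = 0,
                                n_informative: int = 61, n_duplicates: int = 14,
                                n_constant: int = 5):
    """A cohort whose screening outcome is known by construction.

    ``n_informative`` features each load on a shared hazard-driving latent
    (pairwise correlation well below the autocorrelation cutoff), followed
    by exact duplicates of the first ``n_duplicates`` of them (dropped as
    autocorrelated, |r| = 1) and ``n_constant`` zero-variance columns.
    Univariate screening therefore removes exactly
    ``n_duplicates + n_constant`` features.
    """
    rng = np.random.default_rng(seed)
    latent = rng.normal(0.0, 1.0, n)
    cols = {}
    for i in range(n_informative):
        cols[f"c{i + 1:02d}"] = latent + rng.normal(0.0, 0.6, n)
    for i in range(n_duplicates):
        cols[f"dup{i + 1:02d}"] = cols[f"c{i + 1:02d}"].copy()
    for i in range(n_constant):
        cols[f"const{i + 1:02d}"] = np.full(n, float(i))
    features = pd.DataFrame(cols)
    eta = 0.8 * latent
    E = rng.exponential(1.0, n)
    T = 1500.0 * (E / np.exp(eta)) ** (1.0 / 1.2)
    censor = np.minimum(rng.exponential(2500.0, n), ADMIN_CENSOR_DAYS)
    event = (T <= censor).astype(int)
    time = np.maximum(1, np.round(np.minimum(T, censor))).astype(int)
    survival = pd.DataFrame({"time_days": time, "event": event})
    return features, survival


# ---------------------------------------------------------------------------
# Canonical fixtures
# ---------------------------------------------------------------------------

def _contrast_pair_specs():
    """Two phantoms with (near-)equal whole-heart Agatston but very different
    spatial structure: 11 small lesions over 3 territories vs 2 large lesions
    in 1 territory. All lesions are uniform 300 HU boxes, so the Agatston
    score is weight 3 x total in-plane area and equal voxel counts imply
    equal scores."""
    from calciomics.phantoms import LesionSpec, PhantomSpec

    # 11 small 6-voxel boxes (3 x 2 voxels, single slice) over 3 territories
    # vs 2 large 33-voxel boxes (11 x 3 voxels, single slice) in 1 territory:
    # 66 voxels each at uniform 300 HU (weight 3), so whole-heart Agatston is
    # equal (0.25 mm2 x 3 x 66 = 49.5) while the spatial features differ.
    small = (0.9, 0.3, 1.0)
    terr = ["LAD"] * 5 + ["LCX"] * 3 + ["RCA"] * 3
    lesions_a = []
    for li in range(11):
        x = 8.0 + 6.0 * (li % 4)
        y = 8.25 + 6.0 * (li // 4)
        z = 2.5 * (2 + 2 * (li % 3))
        lesions_a.append(LesionSpec(territory=terr[li], center_mm=(x, y, z),
                                    radii_mm=small, peak_hu=300.0, shape="box"))
    spec_a = PhantomSpec(shape=(14, 64, 64), lesions=tuple(lesions_a))
    lesions_b = [
        LesionSpec(territory="LAD", center_mm=(10.0, 10.0, 5.0), radii_mm=(2.6, 0.9, 1.0),
                   peak_hu=300.0, shape="box"),
        LesionSpec(territory="LAD", center_mm=(10.0, 20.0, 12.5), radii_mm=(2.6, 0.9, 1.0),
                   peak_hu=300.0, shape="box"),
    ]
    spec_b = PhantomSpec(shape=(14, 64, 64), lesions=tuple(lesions_b))
    return spec_a, spec_b


def fixture_suite(out_dir: str) -> dict:
    """Write the canonical small fixtures used across the test suite.

    Deterministic: running twice produces byte-identical outputs. Includes
    a zero-calcium phantom (a common, valid patient), a multi-lesion
    phantom, the equal-Agatston/different-structure contrast pair, and a
    small simulated survival cohort.
    """
    from calciomics.phantoms import LesionSpec, PhantomSpec, make_phantom
    from calciomics.volumes import write_volume, write_mask

    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    def _emit(name, spec):
        vol, mask, truth = make_phantom(spec)
        vp = write_volume(vol, os.path.join(out_dir, f"{name}_vol.nii.gz"))
        mp = write_mask(mask, os.path.join(out_dir, f"{name}_mask.nii.gz"),
                        spacing=vol.spacing)
        tp = os.path.join(out_dir, f"{name}_truth.json")
        with open(tp, "w") as fh:
            json.dump(truth, fh, indent=1, default=str)
        paths[name] = {"volume": vp, "mask": mp, "truth": tp}
        return vol, mask, truth

    _emit("zero_calcium", PhantomSpec(shape=(10, 32, 32)))
    multi = PhantomSpec(shape=(20, 64, 64), lesions=(
        LesionSpec("LAD", (10.0, 10.0, 6.0), (2.0, 2.0, 3.0), 450.0),
        LesionSpec("LAD", (10.0, 10.0, 20.0), (1.5, 1.5, 2.8), 250.0),
        LesionSpec("LCX", (22.0, 20.0, 12.0), (2.5, 2.0, 3.0), 800.0),
        LesionSpec("RCA", (8.0, 24.0, 30.0), (1.5, 1.5, 2.8), 1100.0),
    ))
    _emit("multi_lesion", multi)
    spec_a, spec_b = _contrast_pair_specs()
    _emit("contrast_spread", spec_a)
    _emit("contrast_compact", spec_b)

    cohort = CohortSpec(n=300, beta={"f1": 0.5, "f2": -0.4}, n_noise_features=3, seed=11)
    X, surv, _ = simulate_cohort(cohort)
    cp = os.path.join(out_dir, "cohort_small.csv")
    X.merge(surv, on="patient_id").to_csv(cp, index=False)
    paths["cohort_small"] = {"csv": cp}
    return paths
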
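# calciomics

Calcium-omics feature extraction and MACE risk modeling from CT calcium-score
volumes.

## The problem

The whole-heart Agatston score — the clinical standard for quantifying
coronary artery calcium (CAC) on non-contrast cardiac CT — compresses a
patient's entire calcification burden into one number: per-slice calcified
area (mm²) times a density weight (1–4, by the slice's maximum HU bin),
summed over lesions above 130 HU. It ignores how the calcium is arranged:
how many lesions there are, how many coronary territories are involved, how
the lesions spread along each artery, and whether the calcium is dense
("stable") or not. Those spatial and density characteristics carry
pathophysiological signal for major adverse cardiovascular events (MACE).

`calciomics` computes a hierarchy of 80 calcification features from a CT
volume plus a coronary-territory label mask (LM / LAD / LCX / RCA), and turns
them into a single time-to-event risk score:

1. **Detection** — a calcification is a 3D connected component of ≥ 3 voxels
   with HU ≥ 130 inside a coronary territory.
2. **Features** — per lesion (Agatston, mass = c·meanHU·volume, volume, HU
   moments, shape, sequential distances, distance to the top of the volume),
   per territory (score sums, lesion counts, HU statistics and histograms,
   `DistFirst2LastLesionPerArtery`, and *diffusivity* = lesions per mm of
   calcified arterial path, with the conventions diffusivity = 0 for an empty
   territory and 1 for a single lesion), and whole heart.
3. **Risk model** — broad-range features are condensed with ln(1+x);
   univariate Cox screening drops irrelevant (Wald p > 0.2) and highly
   autocorrelated (|r| > 0.95) features; an elastic-net penalized Cox fit
   (mixing α = 0.05, penalty λ = 0.074, tenfold CV available) selects a
   sparse coefficient vector β; the **calcium-omics score** is s = Σᵢ βᵢ·xᵢ,
   used as a single Cox covariate.
4. **Imbalance handling** — a modified SMOTE for censored data up-samples
   event cases (convex interpolation between event-case neighbors, event
   times interpolated too) and down-samples censored cases, on training data
   only.
5. **Evaluation** — Harrell's C-index, fixed-horizon IPCW AUC, Kaplan–Meier
   stratification (five Lipid-Association Agatston groups: 0, 1–99, 100–299,
   300–999, 1000+, with quantile-matched score thresholds), log-rank tests,
   and categorical net reclassification improvement (NRI) with its
   event/non-event decomposition.

Because no patient data ships with the package, everything is exercised on
synthetic phantoms with analytic ground truth (`calciomics.phantoms`) and
simulated survival cohorts with known generative hazards
(`calciomics.cohorts`).

## Worked example

```python
import numpy as np
from calciomics.phantoms import PhantomSpec, LesionSpec, make_phantom
from calciomics.lesions import extract_lesions
from calciomics.features import build_feature_vector

spec = PhantomSpec(shape=(20, 64, 64), lesions=(
    LesionSpec("LAD", (10.0, 10.0, 6.0),  (2.0, 2.0, 3.0), 450.0),
    LesionSpec("LAD", (10.0, 10.0, 20.0), (1.5, 1.5, 2.8), 250.0),
    LesionSpec("LCX", (22.0, 20.0, 12.0), (2.5, 2.0, 3.0), 800.0),
    LesionSpec("RCA", (8.0, 24.0, 30.0),  (1.5, 1.5, 2.8), 1100.0),
))
vol, mask, truth = make_phantom(spec)           # 0.5x0.5 mm in-plane, 2.5 mm slices
vec = build_feature_vector(extract_lesions(vol, mask))
```

prints (selected entries):

```
Agatston                                 231.5000   # == truth["total_agatston"]
MassScore                                101.4688   # mg at c = 0.001 mg/(HU*mm3)
NumLesions                               4.0000
NumCalcifiedArteries                     3.0000
Is_HUmaxAbove1000                        1.0000     # the 1100-HU RCA lesion
Diffusivity_LAD                          0.1442     # 2 lesions / 13.87 mm path
Diffusivity_LM                           0.0000     # empty territory convention
```

The whole-heart Agatston equals the phantom's analytic ground truth exactly:
voxelization is by center-inclusion, so every score is computable in closed
form. On a simulated 1200-patient cohort (≈ 14% MACE events, 6-year
administrative censoring),

```python
from calciomics.cohorts import synthetic_feature_cohort
from calciomics.model import split_cohort, table2_preset
from calciomics.evaluation import c_index

X, surv, _ = synthetic_feature_cohort(n=1200, seed=17)
df = X.merge(surv, on="patient_id")
train, test = split_cohort(df, seed=17)          # 80:20, event-ratio stratified
res = table2_preset(10, train, seed=17)          # calcium-omics + SMOTE sampling
model = res["model"]
print(c_index(model.score(test), test))
```

selects 32 of 61 screened features and gives train/test C-index 76.4 / 73.5
and year-2 AUC 75.1 / 72.7 on this synthetic cohort — the score separates
risk well beyond the single-score baselines (preset 1, Agatston-only, is
available for comparison). The worked hazard contrast: with HR 1.48 per unit
ln(1+NumLesions), going from 1 to 40 lesions multiplies the hazard by
1.48^(ln 41 − ln 2) ≈ 3.27, a **+227%** risk increase.

A command-line interface chains the stages
(`calciomics extract | features | fit | sample | evaluate | simulate | run`);
see `calciomics --help`.

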
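# Methods

## Geometry and detection

Volumes are stored as `(slice, row, col)` arrays of HU with voxel `(i, j, k)`
at local mm position `(k·dx, j·dy, i·dz)`; slice 0 is always the
superior-most slice after read-time normalization (NIfTI/NRRD via SimpleITK,
DICOM series via pydicom with slices sorted by patient z position). All
distances are computed in millimetres, never voxels: calcium scans are
strongly anisotropic (nominally 0.5 × 0.5 mm in-plane, 2.5 mm slices), so
voxel-space distances would be wrong by a factor of five along z.

A calcification is a 3D connected component of voxels with **HU ≥ 130**
(inclusive) inside a non-background territory label, with **≥ 3 voxels**.
Connectivity defaults to 26-neighborhood — 2.5 mm slices make through-plane
adjacency meaningful — and is configurable to 6; the flag documents the
sensitivity of lesion counts to this choice. A component overlapping two
territories takes the majority label; an exact tie breaks to the lowest
territory code with a logged warning. Lesions are ordered within a territory
by centroid z (superior first), ties by (y, x); this fixed "consecutive
sequential order" is what the sequential distance features are defined on.
HU values are used as stored; no resampling or slice interpolation is done.

## Features

**Per lesion.** Agatston = Σ over occupied axial slices of (in-slice area ×
density weight), with the standard weight bins 130–199 → 1, 200–299 → 2,
300–399 → 3, ≥ 400 → 4. No per-slice minimum-area gate is applied beyond the
3-voxel component rule. Mass = c · meanHU · volume with c = 0.001
mg/(HU·mm³) by default; the calibration is configurable and, because ln(1+x)
and Cox are monotone in the covariate, rescaling c changes no model ranking.
Volume is voxel count × voxel volume (no isotropic resampling — a documented
dialect). "First moment" = mean HU and "second moment" = HU variance.
Shape: sphericity = π^⅓(6V)^⅔ / A with A the exposed-face voxel surface
area; elongation = √(λ₁/λ₃) from the covariance of voxel mm coordinates,
λ₃ floored at (min spacing / 2)² so planar/collinear lesions stay finite.
Note the face-count area of a rasterized sphere converges to 3/2 of the
smooth sphere area, so voxel sphericity of a large ball converges to 2/3,
not 1; the face-count definition is kept because it alone guarantees
sphericity < 1 for every voxel shape (a cube attains the maximum ≈ 0.806).

**Per territory.** Score sums, lesion count, population HU statistics over
the territory's voxels (mean, sd, skewness m₃/m₂^1.5, excess kurtosis;
skewness/kurtosis are 0 by convention below n = 3 / n = 4 and for constant
samples), a 5-bin HU histogram with half-open bins at
[130, 200, 300, 400, 1000, ∞), `DistFirst2LastLesionPerArtery` (the summed
sequential centroid path), `DistTop2LastLesion`, and **diffusivity** =
lesions per mm of calcified path, with the boundary conventions 0 (empty
territory) and 1 (single lesion); ≥ 2 lesions with a zero-length path is a
degenerate-geometry error. The diffusivity denominator defaults to the
sequential path and can be switched to the straight first-to-last chord;
`DistTop2LastLesion` measures from the first lesion's centroid projected to
the slice-0 plane by default, with a pure-z alternative.

**The 80-entry vector.** A versioned registry manifest fixes names and
order: 14 whole-heart entries (scores, counts, flags — the dense-calcium
flag `Is_HUmaxAbove1000` uses strict > 1000 by default, ≥ configurable —
mean HU and the 5 histogram bins), 13 entries per territory, and 14
lesion-aggregate statistics (max/mean first moment, skewness and kurtosis of
per-lesion masses, shape aggregates, …). Territory HU statistics are
computed over voxels; lesion-level aggregates are carried separately. A
zero-calcium patient — a large fraction of any screening cohort — yields an
all-zero vector with false flags, which is a valid model input. Absent
supplementary documentation of all 80 names, the registry's composition is
this package's own, pinned in `FeatureRegistry` (exportable as JSON).

## Risk model

ln(1+x) is applied to broad-range non-negative features (scores, counts, HU
magnitudes, distances, histogram counts); flags, sign-indefinite statistics
(skewness/kurtosis), shape ratios, and diffusivity (already compact) stay
raw. Univariate screening drops zero-variance features, features with
univariate Cox Wald p > 0.2 ("irrelevant"), and features with |Pearson r| >
0.95 against an already-retained feature, keeping the member with the
smaller univariate p; both thresholds are defaults of this package (no
published values exist) and are configurable and logged — the audit always
satisfies |dropped| + |retained| = |input|.

Elastic-net penalized Cox selection uses the glmnet convention (mixing
α = 0.05, i.e. ridge-dominant; penalty λ = 0.074 by default; tenfold CV over
the path maximizing held-fold concordance when λ is unset, with event-
stratified folds and seed-incremented refolding if a fold lacks events).
Features are standardized internally and coefficients are reported on the
original transformed scale. The calcium-omics score s = Σ βᵢxᵢ is fit as a
single Cox covariate (matching the "aggregate into one feature" design
rather than refitting all selected features jointly). Cox fits use Efron tie
handling (lifelines) with a tight Newton precision; each model also reports
the partial-likelihood score test statistic at β = 0 (Breslow ties),
which for one binary covariate is the classic log-rank statistic.

Ten preset models mirror the standard comparison ladder: (1) ln(1+Agatston);
(2) ln(1+mass); (3) four territorial masses; (4) mass + ln(1+NumLesions);
(5) mass + the ≥ 2-calcified-arteries flag; (6) mass + the dense-calcium
flag; (7) mass + four territorial top-to-last distances; (8) mass + four
territorial diffusivities; (9) the calcium-omics score; (10) the score with
sampling. Missing feature values are disallowed at model entry (the
extractor never emits them).

## Sampling

The survival-adapted SMOTE is a reconstruction (no published algorithmic
detail exists): synthetic cases interpolate only event–event pairs,
x_new = x_a + u(x_b − x_a) with u ~ U(0,1) and x_b one of the k = 5 nearest
event neighbors in standardized feature space; event times interpolate the
same way (rounded to whole days, floor 1). Censored records are never
synthesized — fabricating censoring times has no defensible generative
model — only down-sampled without replacement. Interpolation happens in the
model's transformed covariate space. Sampling applies to training data only;
the audit verifies synthetic rows are all events, no event was removed, and
no train/test contamination by patient id.

## Evaluation

Harrell's C counts the standard usable pairs with ties at 0.5
(scikit-survival). Fixed-horizon AUC is the IPCW cumulative/dynamic
estimator; inputs are administratively truncated just past the horizon
(statuses up to t unchanged; later records become controls censored at
t + 1 day) because the censoring KM otherwise hits zero at the 6-year
administrative cap, where the estimator is undefined; a naive binary-at-t
ROC AUC is available for comparison. KM curves use the product-limit
estimator with Greenwood intervals and the multivariate log-rank test.
Five-group stratification bins Agatston at exactly-0 / [1,100) / [100,300) /
[300,1000) / [1000,∞) (sub-1 positives join the second bin — a flagged edge
dialect for real-valued scores); score thresholds are the order statistics
matching the reference group sizes (±1 at ties), which makes group
assignments invariant to monotone transforms of the score. The two-group
variant cuts Agatston at 100 and matches the high-risk proportion.
Categorical NRI at horizon t adjudicates status at t, excludes patients
censored before t without an event (raw estimator; a KM-adjusted option
would be a straightforward extension), and bootstraps the total over
patients for a percentile CI; by construction nri_total = nri_events +
nri_nonevents exactly.

## Synthetic data

`make_phantom` voxelizes ellipsoids (or boxes, when exact voxel counts
matter) by **center-inclusion**, so per-lesion voxel counts, areas,
centroids, and hence Agatston/mass/volume have exact closed forms that the
extractor must reproduce bit-for-bit at zero noise; Gaussian HU noise (seeded)
tests robustness, and territory labels cover each lesion plus a 1-voxel
dilation. What the phantoms do *not* emulate: partial-volume blur, beam
hardening, motion, anatomically realistic coronary trees, and non-coronary
calcium — so passing tests demonstrate correctness of the computations, not
scanner-level robustness.

`simulate_cohort` draws features, forms η = β·x (centered), samples
T = scale·(E/e^η)^{1/shape} with E ~ Exp(1) and Weibull shape 1.2 (a mild
aging hazard; any positive shape works for recovery tests), and censors at
min(6 years = 2192 days, exponential dropout with mean 2500 days) — the
administrative cap and roughly the follow-up profile of a multi-year
screening program. When a target event fraction is given (default 14%,
an event-enriched rate), the Weibull scale is calibrated by bisection on the
realized draws. `synthetic_feature_cohort` produces the full 80-column
registry table: ~39% zero-calcium patients, a log-normal severity latent
driving Poisson lesion counts per territory (LAD-dominant mixing), score
magnitudes, HU statistics and the spatial features with the diffusivity
conventions built in; the default hazard raises risk with ln(1+mass) and
ln(1+lesion count) and lowers it for dense (> 1000 HU) calcification,
mirroring the directionality the risk models are meant to detect. These are
covariate generators for the modeling layer; they do not guarantee every
cross-feature identity a real extraction would.

Test problem sizes (200 random ≤ 20³ phantoms for oracle equivalence, 20
seeds at n = 1000–2000 for parameter recovery, 200 seeds for log-rank null
calibration) were chosen as the smallest sizes at which the checked
properties are statistically sharp.

## Numerical choices and limitations

Ties in lesion ordering break on (z, y, x); screening order ties break on
column order; stratification ties shift group membership by at most one.
Agatston weights are undefined below 130 HU by contract. The λ₃ floor makes
elongation scale-dependent for degenerate lesions (intended: it encodes the
slice thickness). The engineered screening cohort realizes its removals as
14 exact-duplicate columns plus 5 zero-variance columns, making the count
deterministic rather than probabilistic. Known limitations: no mass-score
scanner calibration (c is a user parameter); no automatic territory
assignment (masks are inputs); no competing risks or time-varying
covariates; NRI confidence intervals are percentile bootstrap only.
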
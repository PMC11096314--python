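"""MACE risk modeling from calcium-omics feature vectors.

Pipeline: ln(1+x) transform of broad-range features -> univariate Cox
screening (drop irrelevant and highly autocorrelated features) ->
elastic-net penalized Cox selection -> aggregation into a single
calcium-omics score s = sum(beta_i * x_i) -> Cox proportional-hazards fit.

Ten preset Cox models over feature subsets (whole-heart scores, territorial
masses, lesion counts, dense-calcification flag, territorial distances and
diffusivities, and the aggregated calcium-omics score with or without
imbalance-aware sampling) are provided for side-by-side comparison.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from sklearn.model_selection import train_test_split, StratifiedKFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from calciomics.features import FeatureRegistry, default_registry

logger = logging.getLogger(__name__)

TIME_COL = "time_days"
EVENT_COL = "event"

#: Name fragments identifying features that are NOT ln(1+x)-transformed:
#: binary flags and bounded or sign-indefinite statistics.
_NO_TRANSFORM_MARKERS = ("Is_", "skewness", "kurtosis", "Sphericity", "Elongation", "Diffusivity")


def log1_transform(x):
    """ln(1 + x) for non-negative feature values (condenses broad ranges)."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("log1_transform requires non-negative input")
    out = np.log1p(arr)
    return float(out) if np.isscalar(x) else out


def default_transform_set(registry: FeatureRegistry | None = None) -> tuple:
    """Feature names that receive the ln(1+x) transform.

    Scores, counts, HU magnitudes and distances are transformed; flags,
    skewness/kurtosis (sign-indefinite), shape ratios and diffusivity
    (already compact) are used raw.
    """
    registry = registry or default_registry()
    return tuple(
        n for n in registry.names
        if not any(m.lower() in n.lower() for m in _NO_TRANSFORM_MARKERS)
    )


def transform_features(df: pd.DataFrame, transform_set=None) -> pd.DataFrame:
    """Apply ln(1+x) to the configured columns; other columns pass through."""
    if transform_set is None:
        transform_set = default_transform_set()
    out = df.copy()
    for col in transform_set:
        if col in out.columns:
            out[col] = log1_transform(out[col].to_numpy())
    return out


def split_cohort(df: pd.DataFrame, test_fraction: float = 0.2,
                 stratify_by_event: bool = True, seed: int = 0):
    """80:20-style split keeping a similar event ratio in both subsets."""
    ev = df[EVENT_COL].to_numpy()
    if ev.sum() < 2 or (1 - ev).sum() < 2:
        raise ValueError("need >= 2 events and >= 2 censored records to split")
    strat = ev if stratify_by_event else None
    train, test = train_test_split(df, test_size=test_fraction, stratify=strat,
                                   random_state=seed)
    return train, test


# ---------------------------------------------------------------------------
# Univariate screening
# ---------------------------------------------------------------------------

def _univariate_cox_p(x: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    d = pd.DataFrame({"x": x, TIME_COL: time, EVENT_COL: event})
    cph = CoxPHFitter()
    cph.fit(d, duration_col=TIME_COL, event_col=EVENT_COL)
    return float(cph.summary.loc["x", "p"])


def univariate_screen(features: pd.DataFrame, survival: pd.DataFrame,
                      p_keep: float = 0.2, corr_max: float = 0.95):
    """Drop irrelevant and highly autocorrelated features.

    A feature is dropped if (a) it has zero variance, (b) its univariate Cox
    Wald p-value exceeds ``p_keep`` ("irrelevant"), or (c) it has
    |Pearson r| > ``corr_max`` with an already-retained feature ("highly
    autocorrelated" — the member with the smaller univariate p wins).

    Returns ``(retained names, audit)`` where the audit records a reason for
    every dropped feature and ``len(retained) + len(audit) == n features``.
    """
    time = survival[TIME_COL].to_numpy(dtype=float)
    event = survival[EVENT_COL].to_numpy(dtype=int)
    audit: list[dict] = []
    pvals: dict[str, float] = {}
    for name in features.columns:
        x = features[name].to_numpy(dtype=float)
        if np.std(x) == 0.0:
            audit.append({"feature": name, "reason": "zero variance"})
            continue
        try:
            p = _univariate_cox_p(x, time, event)
        except (ConvergenceError, ValueError) as exc:
            audit.append({"feature": name, "reason": f"univariate fit failed: {exc}"})
            continue
        if p > p_keep:
            audit.append({"feature": name, "reason": f"irrelevant (univariate p={p:.3g} > {p_keep})"})
            continue
        pvals[name] = p

    retained: list[str] = []
    for name in sorted(pvals, key=lambda n: (pvals[n], features.columns.get_loc(n))):
        x = features[name].to_numpy(dtype=float)
        partner = None
        for kept in retained:
            r = np.corrcoef(x, features[kept].to_numpy(dtype=float))[0, 1]
            if abs(r) > corr_max:
                partner = (kept, r)
                break
        if partner is None:
            retained.append(name)
        else:
            audit.append({"feature": name,
                          "reason": f"autocorrelated (|r|={abs(partner[1]):.3f} with {partner[0]})"})
    retained = [n for n in features.columns if n in retained]  # original order
    assert len(retained) + len(audit) == features.shape[1]
    return retained, audit


# ---------------------------------------------------------------------------
# Elastic-net selection
# ---------------------------------------------------------------------------

def _surv_y(survival: pd.DataFrame):
    return Surv.from_arrays(event=survival[EVENT_COL].to_numpy(dtype=bool),
                            time=survival[TIME_COL].to_numpy(dtype=float))


def elasticnet_select(features: pd.DataFrame, survival: pd.DataFrame,
                      alpha: float = 0.05, lam: float | None = 0.074,
                      folds: int = 10, seed: int = 0) -> dict:
    """Sparse elastic-net penalized Cox coefficients.

    ``alpha`` is the L1/L2 mixing parameter in the convention where 1 is
    pure lasso (0.05 is therefore ridge-dominant); ``lam`` is the penalty
    strength. Features are standardized internally and the returned
    coefficients are reported on the original (transformed) feature scale.
    With ``lam=None`` the penalty is chosen by k-fold cross-validated
    concordance along the regularization path.
    """
    X = features.to_numpy(dtype=float)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    if np.any(sd == 0):
        bad = [features.columns[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant features reach elastic net (screen first): {bad}")
    Xs = (X - mu) / sd
    y = _surv_y(survival)
    l1_ratio = max(alpha, 1e-6)  # sksurv requires l1_ratio > 0

    if lam is not None:
        model = CoxnetSurvivalAnalysis(l1_ratio=l1_ratio, alphas=[lam], normalize=False)
        model.fit(Xs, y)
        beta_std = model.coef_[:, 0]
        chosen = float(lam)
    else:
        path = CoxnetSurvivalAnalysis(l1_ratio=l1_ratio, n_alphas=30, normalize=False)
        path.fit(Xs, y)
        alphas = path.alphas_
        event = survival[EVENT_COL].to_numpy(dtype=int)
        for attempt in range(10):
            skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + attempt)
            fold_ids = list(skf.split(Xs, event))
            if all(event[tr].sum() > 0 and event[te].sum() > 0 for tr, te in fold_ids):
                break
            logger.info("CV fold without events; refolding with incremented seed")
        from sksurv.metrics import concordance_index_censored
        scores = np.zeros((folds, len(alphas)))
        for f, (tr, te) in enumerate(fold_ids):
            m = CoxnetSurvivalAnalysis(l1_ratio=l1_ratio, alphas=list(alphas), normalize=False)
            m.fit(Xs[tr], y[tr])
            for a_i, a in enumerate(m.alphas_):
                pred = Xs[te] @ m.coef_[:, a_i]
                ev = survival[EVENT_COL].to_numpy(dtype=bool)[te]
                tt = survival[TIME_COL].to_numpy(dtype=float)[te]
                try:
                    scores[f, a_i] = concordance_index_censored(ev, tt, pred)[0]
                except Exception:
                    scores[f, a_i] = 0.5
        chosen = float(alphas[int(np.argmax(scores.mean(axis=0)))])
        model = CoxnetSurvivalAnalysis(l1_ratio=l1_ratio, alphas=[chosen], normalize=False)
        model.fit(Xs, y)
        beta_std = model.coef_[:, 0]

    beta = beta_std / sd
    selected = {features.columns[i]: float(beta[i]) for i in np.flatnonzero(beta_std != 0.0)}
    return {"beta": selected, "lambda": chosen, "alpha": alpha, "folds": folds, "seed": seed}


def calciomics_score(x, beta: dict) -> float | np.ndarray:
    """Aggregated score s = sum(beta_i * x_i) over the selected features."""
    if isinstance(x, pd.DataFrame):
        missing = [n for n in beta if n not in x.columns]
        if missing:
            raise KeyError(f"selected features missing from input: {missing}")
        if not beta:
            return np.zeros(len(x))
        return sum(b * x[n].to_numpy(dtype=float) for n, b in beta.items())
    missing = [n for n in beta if n not in x]
    if missing:
        raise KeyError(f"selected features missing from input: {missing}")
    return float(sum(b * x[n] for n, b in beta.items()))


# ---------------------------------------------------------------------------
# Cox fitting
# ---------------------------------------------------------------------------

def cox_score_test(X: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Cox partial-likelihood score (log-rank) chi-square statistic at beta=0.

    Breslow handling of ties; for a single binary covariate this is the
    classic log-rank test statistic.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(time):
        X = X.T
    order = np.argsort(time, kind="stable")
    X, time, event = X[order], np.asarray(time)[order], np.asarray(event)[order]
    n, p = X.shape
    U = np.zeros(p)
    V = np.zeros((p, p))
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        R = X[at_risk]
        d = int(((time == t) & (event == 1)).sum())
        xbar = R.mean(axis=0)
        U += X[(time == t) & (event == 1)].sum(axis=0) - d * xbar
        cov = (R.T @ R) / len(R) - np.outer(xbar, xbar)
        V += d * cov
    return float(U @ np.linalg.pinv(V) @ U)


@dataclass
class CoxFit:
    """Cox proportional-hazards fit summary (Efron tie handling)."""

    covariates: list
    beta: dict
    hr: dict
    ci_lower: dict
    ci_upper: dict
    p: dict
    logrank_score: float
    n: int
    n_events: int
    fitter: CoxPHFitter = field(repr=False, default=None)

    def predict_partial_hazard_log(self, df: pd.DataFrame) -> np.ndarray:
        return sum(self.beta[c] * df[c].to_numpy(dtype=float) for c in self.covariates)

    def display_summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "HR": {c: round(self.hr[c], 2) for c in self.covariates},
            "CI_lower": {c: round(self.ci_lower[c], 2) for c in self.covariates},
            "CI_upper": {c: round(self.ci_upper[c], 2) for c in self.covariates},
            "p": {c: self.p[c] for c in self.covariates},
        })


def fit_cox(df: pd.DataFrame, covariates: list, time_col: str = TIME_COL,
            event_col: str = EVENT_COL) -> CoxFit:
    """Maximum partial-likelihood Cox fit with Efron ties.

    Reports per-covariate beta, HR = exp(beta), 95% CI and Wald p, plus the
    model score (log-rank) chi-square statistic at beta = 0.
    """
    sub = df[list(covariates) + [time_col, event_col]].copy()
    if sub[event_col].sum() < 1:
        raise ValueError("Cox fit requires at least one event")
    for c in covariates:
        if sub[c].std() == 0:
            raise ValueError(f"constant covariate {c!r}")
    cph = CoxPHFitter()
    try:
        cph.fit(sub, duration_col=time_col, event_col=event_col,
                fit_options={"precision": 1e-9})
    except ConvergenceError as exc:
        raise RuntimeError(f"Cox fit did not converge: {exc}") from exc
    s = cph.summary
    score = cox_score_test(sub[list(covariates)].to_numpy(),
                           sub[time_col].to_numpy(), sub[event_col].to_numpy())
    return CoxFit(
        covariates=list(covariates),
        beta={c: float(s.loc[c, "coef"]) for c in covariates},
        hr={c: float(s.loc[c, "exp(coef)"]) for c in covariates},
        ci_lower={c: float(np.exp(s.loc[c, "coef lower 95%"])) for c in covariates},
        ci_upper={c: float(np.exp(s.loc[c, "coef upper 95%"])) for c in covariates},
        p={c: float(s.loc[c, "p"]) for c in covariates},
        logrank_score=score,
        n=len(sub), n_events=int(sub[event_col].sum()),
        fitter=cph,
    )


def hazard_contrast(hr_per_unit: float, x_ref: float, x_alt: float) -> tuple[float, int]:
    """Hazard ratio and percent risk increase between two covariate values.

    HR = hr_per_unit ** (x_alt - x_ref); the percent increase (HR - 1) * 100
    is rounded to an integer for display.
    """
    hr = float(hr_per_unit) ** (float(x_alt) - float(x_ref))
    return hr, int(round((hr - 1.0) * 100.0))


# ---------------------------------------------------------------------------
# Risk model container and presets
# ---------------------------------------------------------------------------

@dataclass
class RiskModel:
    """Full calcium-omics risk model: transform -> screen -> elastic net -> Cox."""

    transform_set: tuple
    screened_out: list
    retained: list
    beta: dict
    hyperparams: dict
    cox: CoxFit
    score_col: str = "calciomics_score"

    def score(self, raw_features: pd.DataFrame) -> np.ndarray:
        """Calcium-omics score for raw (untransformed) feature rows."""
        x = transform_features(raw_features, self.transform_set)
        return calciomics_score(x, self.beta)

    def to_json(self, path: str) -> str:
        payload = {
            "transform_set": list(self.transform_set),
            "screened_out": self.screened_out,
            "retained": self.retained,
            "beta": self.beta,
            "hyperparams": self.hyperparams,
            "cox": {"covariates": self.cox.covariates, "beta": self.cox.beta,
                    "hr": self.cox.hr, "p": self.cox.p,
                    "logrank_score": self.cox.logrank_score},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
        return path


def fit_calciomics_model(train: pd.DataFrame, feature_names=None,
                         p_keep: float = 0.2, corr_max: float = 0.95,
                         alpha: float = 0.05, lam: float | None = 0.074,
                         folds: int = 10, seed: int = 0,
                         sampling_plan=None) -> RiskModel:
    """Fit the aggregated calcium-omics risk model on a training cohort.

    ``train`` holds raw feature columns plus ``time_days`` and ``event``.
    When ``sampling_plan`` is given, modified-SMOTE up/down sampling is
    applied to the training rows (never to any test data) before the
    elastic-net step.
    """
    registry = default_registry()
    feature_names = list(feature_names or [n for n in registry.names if n in train.columns])
    tset = default_transform_set(registry)
    X = transform_features(train[feature_names], tset)
    surv = train[[TIME_COL, EVENT_COL]].reset_index(drop=True)
    X = X.reset_index(drop=True)

    retained, audit = univariate_screen(X, surv, p_keep=p_keep, corr_max=corr_max)

    work = pd.concat([X[retained], surv], axis=1)
    if sampling_plan is not None:
        from calciomics.sampling import smote_survival
        work = smote_survival(work, sampling_plan, feature_cols=retained)
    sel = elasticnet_select(work[retained], work[[TIME_COL, EVENT_COL]],
                            alpha=alpha, lam=lam, folds=folds, seed=seed)
    beta = sel["beta"]
    score = calciomics_score(work[retained], beta)
    fit_df = pd.DataFrame({"calciomics_score": score,
                           TIME_COL: work[TIME_COL], EVENT_COL: work[EVENT_COL]})
    cox = fit_cox(fit_df, ["calciomics_score"])
    return RiskModel(transform_set=tset, screened_out=audit, retained=retained,
                     beta=beta, hyperparams={"alpha": alpha, "lambda": sel["lambda"],
                                             "folds": folds, "seed": seed,
                                             "p_keep": p_keep, "corr_max": corr_max},
                     cox=cox)


#: Covariate builders for the ten preset Cox models. ``L`` marks ln(1+x).
_PRESETS = {
    1: ("Agatston score", [("Agatston", True)]),
    2: ("Mass score", [("MassScore", True)]),
    3: ("Arterial mass scores", [(f"Mass_{t}", True) for t in ("LM", "LAD", "LCX", "RCA")]),
    4: ("Number of lesions", [("MassScore", True), ("NumLesions", True)]),
    5: ("Number of calcified arteries", [("MassScore", True), ("Is_CalcifiedArteries_ge2", False)]),
    6: ("Dense calcification flag", [("MassScore", True), ("Is_HUmaxAbove1000", False)]),
    7: ("Lesions' distance (top to last)", [("MassScore", True)] +
        [(f"DistTop2LastLesion_{t}", False) for t in ("LM", "LAD", "LCX", "RCA")]),
    8: ("Territorial diffusivity", [("MassScore", True)] +
        [(f"Diffusivity_{t}", False) for t in ("LM", "LAD", "LCX", "RCA")]),
}


def table2_preset(preset: int, train: pd.DataFrame, seed: int = 0,
                  sampling_plan=None, **model_kwargs):
    """Fit one of the ten preset risk models on a training cohort.

    Presets 1-8 are fixed covariate subsets (fit directly by Cox); preset 9
    is the aggregated calcium-omics score and preset 10 the same with
    modified-SMOTE sampling of the training data.
    """
    if preset in _PRESETS:
        label, spec = _PRESETS[preset]
        cols = []
        df = pd.DataFrame(index=train.index)
        for name, do_log in spec:
            col = f"ln1p_{name}" if do_log else name
            df[col] = log1_transform(train[name].to_numpy()) if do_log else train[name]
            cols.append(col)
        df[TIME_COL] = train[TIME_COL]
        df[EVENT_COL] = train[EVENT_COL]
        usable = [c for c in cols if df[c].std() > 0]
        if not usable:
            raise ValueError(f"preset {preset}: all covariates constant on this cohort")
        return {"preset": preset, "label": label, "cox": fit_cox(df, usable),
                "covariates": usable}
    if preset == 9:
        model = fit_calciomics_model(train, seed=seed, sampling_plan=None, **model_kwargs)
        return {"preset": 9, "label": "Calcium-omics", "model": model, "cox": model.cox}
    if preset == 10:
        if sampling_plan is None:
            from calciomics.sampling import SamplingPlan
            sampling_plan = SamplingPlan(target_event_fraction=0.5, seed=seed)
        model = fit_calciomics_model(train, seed=seed, sampling_plan=sampling_plan, **model_kwargs)
        return {"preset": 10, "label": "Calcium-omics (with sampling)", "model": model,
                "cox": model.cox}
    raise ValueError(f"unknown preset {preset!r} (valid: 1..10)")
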
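"""Time-to-event evaluation and risk stratification.

Implements Harrell's concordance index, fixed-horizon cumulative/dynamic
AUC (IPCW-weighted), Kaplan-Meier group curves with log-rank tests,
five-group Lipid-Association Agatston stratification with quantile-matched
calcium-omics thresholds, two-group stratification, categorical net
reclassification improvement (NRI) with its event / non-event
decomposition, and the fraction of events captured by the top risk group.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from sksurv.metrics import concordance_index_censored, cumulative_dynamic_auc
from sksurv.util import Surv

DAYS_PER_YEAR = 365.25

#: Lipid-Association five-group Agatston bin edges: score exactly 0; then
#: [1, 100), [100, 300), [300, 1000), [1000, inf). Real-valued sub-1
#: positives join the second bin.
AGATSTON5_EDGES = (1.0, 100.0, 300.0, 1000.0)


def _arrays(survival: pd.DataFrame):
    return (survival["time_days"].to_numpy(dtype=float),
            survival["event"].to_numpy(dtype=int))


def c_index(scores, survival: pd.DataFrame) -> float:
    """Harrell's concordance index as a percentage (higher score = risk).

    Usable pairs follow the standard definition (event-before-censor and
    event-before-event orderings); score ties count 0.5. Raises if no pair
    is comparable.
    """
    time, event = _arrays(survival)
    c, n_concordant, n_discordant, n_tied, _ = concordance_index_censored(
        event.astype(bool), time, np.asarray(scores, dtype=float))
    if n_concordant + n_discordant + n_tied == 0:
        raise ValueError("no comparable pairs: concordance undefined")
    return float(c) * 100.0


def auc_at_time(scores, survival: pd.DataFrame, t_years: float,
                censoring_survival: pd.DataFrame | None = None,
                estimator: str = "ipcw") -> float:
    """Cumulative/dynamic AUC (%) at a fixed horizon.

    Cases are patients with an event by ``t_years``, controls those still
    at risk beyond it. The default estimator weights by the inverse
    probability of censoring (KM of the censoring distribution, estimated
    on ``censoring_survival`` or the evaluation cohort itself); the naive
    ``binary`` estimator scores the plain ROC AUC of the event-by-t label
    among patients with known status.
    """
    t = float(t_years) * DAYS_PER_YEAR
    time, event = _arrays(survival)
    if not np.any((event == 1) & (time <= t)):
        raise ValueError(f"no events by t={t_years} years: AUC undefined")
    if not np.any(time > t):
        raise ValueError(f"no patients at risk beyond t={t_years} years: AUC undefined")
    scores = np.asarray(scores, dtype=float)
    if estimator == "binary":
        known = (time > t) | (event == 1)
        label = ((event == 1) & (time <= t))[known]
        from sklearn.metrics import roc_auc_score
        return float(roc_auc_score(label, scores[known])) * 100.0
    if estimator != "ipcw":
        raise ValueError(f"unknown estimator {estimator!r}")
    ref = censoring_survival if censoring_survival is not None else survival
    rt, re = _arrays(ref)

    def _truncate(tt, ee):
        # administrative truncation just past the horizon: anyone still at
        # risk after t becomes a control censored at tau; statuses up to t
        # are untouched. Keeps the censoring KM positive over [0, t].
        tau = t + 1.0
        return np.where(tt > t, tau, tt), (ee == 1) & (tt <= t)

    rt_c, re_c = _truncate(rt, re)
    tt_c, ee_c = _truncate(time, event)
    y_train = Surv.from_arrays(event=re_c, time=rt_c)
    y_test = Surv.from_arrays(event=ee_c, time=tt_c)
    auc, _ = cumulative_dynamic_auc(y_train, y_test, scores, [t])
    return float(auc[0]) * 100.0


def km_estimate(survival: pd.DataFrame, groups=None) -> dict:
    """Kaplan-Meier curves per group plus a log-rank test across groups.

    Returns ``{"curves": {group: DataFrame(time, survival, ci_lower,
    ci_upper)}, "logrank_statistic", "logrank_p"}``; with a single group the
    test entries are None.
    """
    time, event = _arrays(survival)
    if groups is None:
        groups = np.zeros(len(time), dtype=int)
    groups = np.asarray(groups)
    curves = {}
    for g in np.unique(groups):
        m = groups == g
        if not m.any():
            raise ValueError(f"empty group {g}")
        kmf = KaplanMeierFitter()
        kmf.fit(time[m], event[m])
        ci = kmf.confidence_interval_survival_function_
        curves[g] = pd.DataFrame({
            "time": kmf.survival_function_.index.to_numpy(),
            "survival": kmf.survival_function_["KM_estimate"].to_numpy(),
            "ci_lower": ci.iloc[:, 0].to_numpy(),
            "ci_upper": ci.iloc[:, 1].to_numpy(),
        })
    if len(curves) > 1:
        res = multivariate_logrank_test(time, groups, event)
        stat, p = float(res.test_statistic), float(res.p_value)
    else:
        stat, p = None, None
    return {"curves": curves, "logrank_statistic": stat, "logrank_p": p}


def _agatston5_group(agatston: np.ndarray) -> np.ndarray:
    g = np.zeros(len(agatston), dtype=int)
    g[agatston > 0] = 1          # sub-1 positives join the 1-99 bin
    g[agatston >= AGATSTON5_EDGES[1]] = 2
    g[agatston >= AGATSTON5_EDGES[2]] = 3
    g[agatston >= AGATSTON5_EDGES[3]] = 4
    return g


def stratify_matched(reference: np.ndarray, target: np.ndarray) -> dict:
    """Five-group stratification: fixed Agatston bins, quantile-matched score.

    The reference (Agatston) is grouped by the Lipid-Association bins; the
    target score is cut at its own order statistics so each target group
    holds the same number of patients as the corresponding reference group
    (ties may shift membership by one).
    """
    reference = np.asarray(reference, dtype=float)
    target = np.asarray(target, dtype=float)
    if len(reference) != len(target):
        raise ValueError("reference and target must cover the same cohort")
    if np.ptp(target) == 0:
        raise ValueError("degenerate score: all values equal, cannot set thresholds")
    ref_groups = _agatston5_group(reference)
    counts = np.bincount(ref_groups, minlength=5)
    order = np.argsort(target, kind="stable")
    tgt_groups = np.empty(len(target), dtype=int)
    start = 0
    thresholds = []
    for g in range(5):
        stop = start + counts[g]
        tgt_groups[order[start:stop]] = g
        if g < 4:
            thresholds.append(float(target[order[stop - 1]]) if stop > 0 else -np.inf)
        start = stop
    return {"reference_groups": ref_groups, "target_groups": tgt_groups,
            "reference_edges": (0.0,) + AGATSTON5_EDGES, "target_thresholds": thresholds,
            "group_counts": counts.tolist()}


def stratify_two_group(reference: np.ndarray, target: np.ndarray,
                       reference_cut: float = 100.0) -> dict:
    """Two-group (low/high) stratification with matched proportions.

    The reference is cut at ``reference_cut`` (Agatston 100 by default);
    the target threshold is the order statistic giving the same number of
    high-risk patients.
    """
    reference = np.asarray(reference, dtype=float)
    target = np.asarray(target, dtype=float)
    ref_groups = (reference >= reference_cut).astype(int)
    n_high = int(ref_groups.sum())
    order = np.argsort(target, kind="stable")
    tgt_groups = np.zeros(len(target), dtype=int)
    if n_high > 0:
        tgt_groups[order[len(target) - n_high:]] = 1
        threshold = float(target[order[len(target) - n_high]])
    else:
        threshold = float("inf")
    return {"reference_groups": ref_groups, "target_groups": tgt_groups,
            "reference_cut": reference_cut, "target_threshold": threshold}


def categorical_nri(old_groups, new_groups, survival: pd.DataFrame,
                    t_years: float, n_bootstrap: int = 0, seed: int = 0) -> dict:
    """Categorical net reclassification improvement at a fixed horizon.

    ``nri_events`` = P(up | event) - P(down | event); ``nri_nonevents`` =
    P(down | nonevent) - P(up | nonevent); ``nri_total`` is their sum.
    Events are adjudicated at ``t_years``: a patient censored before the
    horizon without an event has unknown status and is excluded from the
    raw estimator. Optional percentile bootstrap over patients gives a CI
    for the total.
    """
    old_groups = np.asarray(old_groups)
    new_groups = np.asarray(new_groups)
    time, event = _arrays(survival)
    t = float(t_years) * DAYS_PER_YEAR
    is_event = (event == 1) & (time <= t)
    is_nonevent = time > t
    known = is_event | is_nonevent

    def _components(mask_e, mask_ne, old, new):
        if mask_e.sum() == 0:
            raise ValueError("no events by the horizon: NRI_events undefined")
        if mask_ne.sum() == 0:
            raise ValueError("no nonevents at the horizon: NRI_nonevents undefined")
        up = new > old
        down = new < old
        nri_e = (up[mask_e].mean() - down[mask_e].mean())
        nri_ne = (down[mask_ne].mean() - up[mask_ne].mean())
        return float(nri_e), float(nri_ne)

    nri_e, nri_ne = _components(is_event, is_nonevent, old_groups, new_groups)
    out = {"nri_events": nri_e, "nri_nonevents": nri_ne, "nri_total": nri_e + nri_ne,
           "n_events": int(is_event.sum()), "n_nonevents": int(is_nonevent.sum()),
           "n_excluded": int((~known).sum())}
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        totals = []
        n = len(old_groups)
        for _ in range(n_bootstrap):
            idx = rng.integers(0, n, size=n)
            try:
                e, ne = _components(is_event[idx], is_nonevent[idx],
                                    old_groups[idx], new_groups[idx])
                totals.append(e + ne)
            except ValueError:
                continue
        if totals:
            lo, hi = np.percentile(totals, [2.5, 97.5])
            out["ci_95"] = (float(lo), float(hi))
    return out


def high_risk_capture(groups, survival: pd.DataFrame, t_years: float) -> float:
    """Percent of horizon events whose assignment is the highest-risk group."""
    groups = np.asarray(groups)
    time, event = _arrays(survival)
    t = float(t_years) * DAYS_PER_YEAR
    is_event = (event == 1) & (time <= t)
    if is_event.sum() == 0:
        raise ValueError("no events by the horizon")
    top = groups.max()
    return float((groups[is_event] == top).mean()) * 100.0


def plot_km(km_result: dict, path: str, title: str = "MACE-free survival") -> str:
    """Save Kaplan-Meier step curves (one line per risk group) as an image."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for g, curve in sorted(km_result["curves"].items()):
        ax.step(curve["time"] / DAYS_PER_YEAR, curve["survival"], where="post",
                label=f"group {g}")
    ax.set_xlabel("years")
    ax.set_ylabel("MACE-free probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path
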
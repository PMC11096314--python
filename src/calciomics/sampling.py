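"""Imbalance-aware resampling for censored survival training data.

MACE cohorts are heavily imbalanced (event rates around 10-15%), which
starves penalized Cox fits of events. This module implements a modified
SMOTE for censored data: synthetic *event* cases are generated by convex
interpolation between an event case and one of its k nearest event-case
neighbors in standardized feature space (event times interpolated the same
way), while censored cases are down-sampled without replacement. Censored
records are never synthesized, so no censoring times are fabricated.

Sampling applies to training data only; the test split is never touched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from calciomics.model import TIME_COL, EVENT_COL


@dataclass(frozen=True)
class SamplingPlan:
    """How to rebalance a training cohort.

    Attributes
    ----------
    target_event_fraction : float in (0, 1)
        Desired event fraction after sampling; used to derive
        ``n_synthetic`` when that is not given explicitly.
    k_neighbors : int
        Neighborhood size for SMOTE interpolation partners.
    n_synthetic : int or None
        Explicit number of synthetic event cases; derived from the target
        fraction when None.
    downsample_fraction : float in (0, 1]
        Fraction of censored cases kept (sampled without replacement).
    seed : int
        Fixes neighbor choice, interpolation weights and down-sampling.
    """

    target_event_fraction: float = 0.5
    k_neighbors: int = 5
    n_synthetic: int | None = None
    downsample_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.target_event_fraction < 1.0):
            raise ValueError("target_event_fraction must be in (0, 1)")
        if not (0.0 < self.downsample_fraction <= 1.0):
            raise ValueError("downsample_fraction must be in (0, 1]")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


def _resolve_counts(n_events: int, n_censored: int, plan: SamplingPlan) -> tuple[int, int]:
    """Number of synthetic events and retained censored cases for a plan."""
    n_keep_cens = int(round(n_censored * plan.downsample_fraction))
    if plan.n_synthetic is not None:
        return plan.n_synthetic, n_keep_cens
    f = plan.target_event_fraction
    # choose n_syn so (n_events + n_syn) / (n_events + n_syn + n_keep_cens) ~= f
    target_events = f * n_keep_cens / (1.0 - f)
    n_syn = int(round(target_events)) - n_events
    if n_syn < 0:
        achievable = n_events / (n_events + n_keep_cens) if (n_events + n_keep_cens) else 0.0
        raise ValueError(
            f"target event fraction {f} below the {achievable:.3f} already achieved; "
            "down-sampling never removes event cases")
    return n_syn, n_keep_cens


def smote_survival(train: pd.DataFrame, plan: SamplingPlan,
                   feature_cols: list | None = None) -> pd.DataFrame:
    """Augment a training cohort per a :class:`SamplingPlan`.

    ``train`` holds feature columns (already in the model's transformed
    covariate space) plus ``time_days`` and ``event``. Synthetic rows are
    flagged with ``is_synthetic = 1`` and always carry ``event = 1``; their
    times are interpolated and rounded to whole days (floor 1).
    """
    rng = np.random.default_rng(plan.seed)
    if feature_cols is None:
        feature_cols = [c for c in train.columns
                        if c not in (TIME_COL, EVENT_COL, "is_synthetic", "patient_id")]
    events = train[train[EVENT_COL] == 1]
    censored = train[train[EVENT_COL] == 0]
    n_syn, n_keep_cens = _resolve_counts(len(events), len(censored), plan)

    if n_syn > 0 and len(events) < plan.k_neighbors + 1:
        raise ValueError(
            f"need >= k_neighbors + 1 = {plan.k_neighbors + 1} event cases, have {len(events)}")

    synthetic_rows = []
    if n_syn > 0:
        X = events[feature_cols].to_numpy(dtype=float)
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd[sd == 0] = 1.0
        Xs = (X - mu) / sd
        nn = NearestNeighbors(n_neighbors=plan.k_neighbors + 1).fit(Xs)
        _, neigh = nn.kneighbors(Xs)
        times = events[TIME_COL].to_numpy(dtype=float)
        for _ in range(n_syn):
            a = int(rng.integers(len(events)))
            b = int(neigh[a][1:][int(rng.integers(plan.k_neighbors))])
            u = float(rng.uniform())
            x_new = X[a] + u * (X[b] - X[a])
            t_new = max(1, int(round(times[a] + u * (times[b] - times[a]))))
            row = dict(zip(feature_cols, x_new))
            row[TIME_COL] = t_new
            row[EVENT_COL] = 1
            row["is_synthetic"] = 1
            synthetic_rows.append(row)

    if n_keep_cens < len(censored):
        keep_idx = rng.choice(len(censored), size=n_keep_cens, replace=False)
        censored = censored.iloc[np.sort(keep_idx)]

    # real rows keep their original relative order; synthetic rows append
    real = train.loc[train.index.isin(events.index) | train.index.isin(censored.index)]
    out = real.copy()
    if "is_synthetic" not in out.columns:
        out["is_synthetic"] = 0
    if synthetic_rows:
        out = pd.concat([out, pd.DataFrame(synthetic_rows)], axis=0, ignore_index=False)
    out = out.reset_index(drop=True)
    out["is_synthetic"] = out["is_synthetic"].fillna(0).astype(int)
    return out


def audit_sampling(before: pd.DataFrame, after: pd.DataFrame,
                   test: pd.DataFrame | None = None) -> dict:
    """Report sampling effects and verify the contract.

    Checks that every synthetic record is an event, that no event case was
    removed, and — when a test split is given — that no training patient_id
    leaks into the test set and the test set holds no synthetic rows.
    """
    syn = after[after.get("is_synthetic", pd.Series(0, index=after.index)) == 1]
    if len(syn) and not (syn[EVENT_COL] == 1).all():
        raise AssertionError("synthetic record with event != 1")
    n_ev_before = int((before[EVENT_COL] == 1).sum())
    real = after[after.get("is_synthetic", pd.Series(0, index=after.index)) == 0]
    n_ev_after_real = int((real[EVENT_COL] == 1).sum())
    if n_ev_after_real < n_ev_before:
        raise AssertionError("sampling removed event cases")
    report = {
        "n_before": len(before),
        "n_after": len(after),
        "n_synthetic": int(len(syn)),
        "event_fraction_before": float((before[EVENT_COL] == 1).mean()),
        "event_fraction_after": float((after[EVENT_COL] == 1).mean()),
    }
    if test is not None:
        if "is_synthetic" in test.columns and (test["is_synthetic"] == 1).any():
            raise AssertionError("synthetic record found in test set")
        if "patient_id" in test.columns and "patient_id" in after.columns:
            shared = set(after["patient_id"]) & set(test["patient_id"])
            if shared:
                raise AssertionError(f"patient ids shared across train/test: {sorted(shared)[:5]}")
        report["test_contamination"] = False
    return report
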
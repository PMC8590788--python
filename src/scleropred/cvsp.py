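"""Cross-Validated Sequential Prediction (CVSP).

Patients are partitioned into F folds (default 5); the multivariate
mixed model (with its quantile transforms and anchors) is fitted once
per fold on the other F-1 folds.  A held-out patient's risk is then
computed per visit with no refitting: walking the patient's pooled
observation times from first to last (regardless of which biomarker was
measured when), each step conditions on the history strictly before the
next observation time and emits the closed-form conditional moments and
event probabilities, starting with a cold-start prediction at the first
visit.  Because predictions always come from the fold model that
excluded the patient, pooled performance metrics (CV-AUC with a DeLong
confidence interval) are honest estimates of out-of-sample accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .data_model import LongitudinalDataset
from .design import group_visits
from .model import BayesianMVLMM

__all__ = [
    "assign_folds",
    "fit_fold_models",
    "sequential_predict",
    "cv_auc",
    "delong_auc_ci",
    "auc_by_history_count",
    "run_cvsp",
]


def assign_folds(ds: LongitudinalDataset, n_folds: int = 5, seed: int = 0) -> dict:
    """Patient-level random partition into folds of near-equal size."""
    ids = list(ds.patient_ids)
    if n_folds > len(ids):
        raise ValueError(f"{n_folds} folds but only {len(ids)} patients")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    folds = {}
    for rank, idx in enumerate(perm):
        folds[ids[idx]] = rank % n_folds
    return folds


def fit_fold_models(
    ds: LongitudinalDataset,
    folds: dict,
    model_factory=None,
    **model_kwargs,
) -> dict[int, BayesianMVLMM]:
    """Fit one model per fold on the training complement of that fold.

    Each fold model refits its own quantile transforms and random-effect
    anchors on training-fold data only, so no held-out information leaks
    into the preprocessing.
    """
    fold_ids = sorted(set(folds.values()))
    models = {}
    for f in fold_ids:
        train_ids = [pid for pid, ff in folds.items() if ff != f]
        train_ds = ds.subset(train_ids)
        model = model_factory() if model_factory else BayesianMVLMM(**model_kwargs)
        models[f] = model.fit(train_ds)
    return models


def sequential_predict(
    ds: LongitudinalDataset,
    folds: dict,
    fold_models: dict[int, BayesianMVLMM],
    visit_tolerance: float = 1.0 / 365.25,
) -> pd.DataFrame:
    """Per-visit held-out predictions for every patient.

    For a patient with n pooled visit times this emits exactly n
    instances: the cold-start prediction of the first visit and one
    advance per subsequent visit.  Observed event labels come from the
    biomarker actually measured at the target visit; events whose
    measure was not observed there are left NaN (excluded from that
    event's AUC).
    """
    rows = []
    events = ds.events
    for pid in ds.patient_ids:
        if pid not in folds:
            raise KeyError(f"patient {pid!r} missing from fold assignment")
        model = fold_models[folds[pid]]
        obs = ds.patient_observations(pid)
        t = obs["time_years"].to_numpy()
        meas = obs["measure"].to_numpy()
        vals = obs["value"].to_numpy()
        order = np.argsort(t, kind="mergesort")
        t, meas, vals = t[order], meas[order], vals[order]
        vid = group_visits(t, visit_tolerance)
        n_visits = vid[-1] + 1 if len(vid) else 0
        visit_times = np.array([t[vid == v].mean() for v in range(n_visits)])
        cov_row = ds.covariates.loc[[pid]]
        for j in range(n_visits):
            target = visit_times[j]
            hist = t < (target - 1e-12)
            res = model.predict_instance(
                cov_row, t[hist], meas[hist], vals[hist], float(target),
                patient_id=pid,
            )
            row = {
                "patient_id": pid,
                "fold": folds[pid],
                "visit_index": j,
                "target_time": float(target),
                "n_history": int(hist.sum()),
            }
            at_target = vid == j
            for m in ds.measures:
                row[f"n_prior_{m}"] = int((meas[hist] == m).sum())
                sel = at_target & (meas == m)
                row[f"obs_value_{m}"] = float(vals[sel].mean()) if sel.any() else np.nan
            for k, m in enumerate(ds.measures):
                row[f"pred_mean_z_{m}"] = res.cond_mean[k]
                row[f"pred_sd_z_{m}"] = float(np.sqrt(max(res.cond_cov[k, k], 0.0)))
            for ev in events:
                row[f"p_{ev.label}"] = res.event_probs[ev.label]
                ov = row[f"obs_value_{ev.measure}"]
                row[f"obs_{ev.label}"] = (
                    float(ev.indicator(np.asarray([ov]))[0]) if np.isfinite(ov) else np.nan
                )
            rows.append(row)
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
def delong_auc_ci(labels: np.ndarray, scores: np.ndarray, alpha: float = 0.05):
    """AUC with DeLong variance and normal-approximation CI.

    Midrank (trapezoidal) tie handling; the CI is computed on the logit
    scale and mapped back so it stays inside [0, 1].
    """
    y = np.asarray(labels, dtype=float)
    s = np.asarray(scores, dtype=float)
    pos = s[y == 1]
    neg = s[y == 0]
    n1, n0 = len(pos), len(neg)
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: both classes must be present")
    all_s = np.concatenate([pos, neg])
    ranks = pd.Series(all_s).rank(method="average").to_numpy()
    r1 = ranks[:n1]
    auc = (r1.sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    # structural components
    pos_ranks = pd.Series(pos).rank(method="average").to_numpy()
    neg_ranks = pd.Series(neg).rank(method="average").to_numpy()
    v10 = (r1 - pos_ranks) / n0
    v01 = 1.0 - (ranks[n1:] - neg_ranks) / n1
    var = (np.var(v10, ddof=1) / n1 if n1 > 1 else 0.0) + (
        np.var(v01, ddof=1) / n0 if n0 > 1 else 0.0
    )
    se = float(np.sqrt(max(var, 0.0)))
    zq = -ndtri(alpha / 2)
    if 0.0 < auc < 1.0 and se > 0:
        logit = np.log(auc / (1 - auc))
        se_logit = se / (auc * (1 - auc))
        lo = 1 / (1 + np.exp(-(logit - zq * se_logit)))
        hi = 1 / (1 + np.exp(-(logit + zq * se_logit)))
    else:
        lo = max(auc - zq * se, 0.0)
        hi = min(auc + zq * se, 1.0)
    return float(auc), float(lo), float(hi), se


def cv_auc(report: pd.DataFrame, event_label: str, alpha: float = 0.05) -> dict:
    """Pooled cross-validated AUC for one event over all usable instances."""
    p = report[f"p_{event_label}"].to_numpy(dtype=float)
    y = report[f"obs_{event_label}"].to_numpy(dtype=float)
    keep = np.isfinite(y) & np.isfinite(p)
    p, y = p[keep], y[keep]
    if len(np.unique(y)) < 2:
        raise ValueError(f"AUC undefined for {event_label}: single-class labels")
    auc, lo, hi, se = delong_auc_ci(y, p, alpha)
    return {
        "event": event_label,
        "auc": auc,
        "ci_low": lo,
        "ci_high": hi,
        "se": se,
        "n_instances": int(len(y)),
        "n_events": int(y.sum()),
    }


def auc_by_history_count(
    report: pd.DataFrame, event_label: str, measure: str,
    bins=((0, 0), (1, 1), (2, 2), (3, np.inf)),
) -> pd.DataFrame:
    """AUC stratified by how many prior observations of the predicted
    measure the patient had (0, 1, 2, >2)."""
    rows = []
    cnt = report[f"n_prior_{measure}"].to_numpy()
    for lo, hi in bins:
        sub = report[(cnt >= lo) & (cnt <= hi)]
        label = f"{lo}" if lo == hi else f">{lo - 1}"
        try:
            res = cv_auc(sub, event_label)
        except ValueError:
            res = {"auc": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                   "n_instances": len(sub), "n_events": int(np.nansum(sub[f"obs_{event_label}"]))}
        res["n_prior"] = label
        rows.append(res)
    return pd.DataFrame(rows)


def run_cvsp(
    ds: LongitudinalDataset,
    n_folds: int = 5,
    seed: int = 0,
    **model_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """End-to-end CVSP: folds, fold fits, sequential predictions, AUC table."""
    folds = assign_folds(ds, n_folds, seed)
    models = fit_fold_models(ds, folds, **model_kwargs)
    report = sequential_predict(ds, folds, models)
    summary = []
    for ev in ds.events:
        try:
            summary.append(cv_auc(report, ev.label))
        except ValueError:
            summary.append({"event": ev.label, "auc": np.nan, "n_instances": 0,
                            "n_events": 0})
    return report, pd.DataFrame(summary).set_index("event")
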
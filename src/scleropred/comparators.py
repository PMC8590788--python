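"""Baseline event-prediction models: nested logistic regressions and a
random forest.

These models predict the event at a patient's next observation of a
measure directly from simple history summaries, the standard alternative
to modeling the biomarker process itself:

    LM1: logit P(E_next) = ns(y_last, 2) + recent other measures + covariates
    LM2: LM1 + ns(y_prev, 2)
    LM3: LM2 + count of past events of the measure

The random forest uses the same covariate set as LM3 and is evaluated on
out-of-bag (OOB) probabilities.  Missing predictors (e.g. no second-to-
last value yet) are completed by iterative conditional (chained-
equations-style) multiple imputation; predicted probabilities are
averaged across completions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer
from sklearn.linear_model import LogisticRegression

from .cvsp import delong_auc_ci
from .data_model import EventDefinition, LongitudinalDataset
from .design import CovariateEncoder, NaturalSplineFeature

__all__ = [
    "build_event_table",
    "impute_covariates",
    "fit_logistic_suite",
    "fit_random_forest",
    "RandomForestSettings",
]

LM_VARIANTS = ("LM1", "LM2", "LM3")


def build_event_table(
    ds: LongitudinalDataset,
    events: list[EventDefinition] | None = None,
    visit_tolerance: float = 1.0 / 365.25,
) -> pd.DataFrame:
    """One row per (event, patient, target visit) with the event's measure
    observed at the target.

    Visits are the patient's pooled observation times (same grouping as
    sequential prediction); a patient's first visit has no predictors and
    contributes no rows.  The outcome is the event indicator of the
    measure's value at the target visit; predictors are the most recent
    (y_last) and second most recent (y_prev) prior values of that
    measure, the most recent prior value of every other measure, the
    count of past events of the measure, and baseline covariates.
    Predictors that do not exist yet are kept as NaN for downstream
    multiple imputation — direct event models cannot use a history they
    have not observed, which is exactly where joint biomarker modeling
    has its edge.
    """
    from .design import group_visits

    events = events if events is not None else ds.events
    enc = CovariateEncoder()
    cov_design = enc.encode(ds.covariates)
    cov_map = {pid: cov_design[i] for i, pid in enumerate(ds.patient_ids)}
    cov_names = enc.column_names

    rows = []
    for pid in ds.patient_ids:
        obs = ds.patient_observations(pid)
        t_all = obs["time_years"].to_numpy()
        m_all = obs["measure"].to_numpy()
        v_all = obs["value"].to_numpy()
        order = np.argsort(t_all, kind="mergesort")
        t_all, m_all, v_all = t_all[order], m_all[order], v_all[order]
        vid = group_visits(t_all, visit_tolerance)
        n_visits = vid[-1] + 1 if len(vid) else 0
        visit_times = np.array([t_all[vid == v].mean() for v in range(n_visits)])
        for ev in events:
            sel_k = m_all == ev.measure
            ind_all = ev.indicator(v_all)
            for v in range(1, n_visits):
                at_target = sel_k & (vid == v)
                if not at_target.any():
                    continue
                target_value = float(v_all[at_target].mean())
                prior_k = sel_k & (vid < v)
                prior_vals = v_all[prior_k]
                row = {
                    "event": ev.label,
                    "measure": ev.measure,
                    "patient_id": pid,
                    "target_time": float(visit_times[v]),
                    "outcome": float(ev.indicator(np.asarray([target_value]))[0]),
                    "y_last": float(prior_vals[-1]) if len(prior_vals) >= 1 else np.nan,
                    "y_prev": float(prior_vals[-2]) if len(prior_vals) >= 2 else np.nan,
                    "prior_count": float(ind_all[prior_k].sum()),
                }
                for m in ds.measures:
                    if m == ev.measure:
                        continue
                    other = (m_all == m) & (vid < v)
                    row[f"recent_{m}"] = (
                        float(v_all[other][-1]) if other.any() else np.nan
                    )
                for name, val in zip(cov_names, cov_map[pid]):
                    if name != "intercept":
                        row[name] = float(val)
                rows.append(row)
    return pd.DataFrame(rows)


def _predictor_columns(table: pd.DataFrame) -> list[str]:
    skip = {"event", "measure", "patient_id", "target_time", "outcome"}
    return [c for c in table.columns if c not in skip]


def impute_covariates(
    table: pd.DataFrame, m: int = 5, seed: int = 0, max_iter: int = 10
) -> list[pd.DataFrame]:
    """m completed copies of the event table by iterative conditional
    imputation (posterior-sampled regressions per column)."""
    if m == 1:
        warnings.warn("m=1 degenerates to single imputation", stacklevel=2)
    cols = _predictor_columns(table)
    X = table[cols].to_numpy(dtype=float)
    fully_missing = [c for c, col in zip(cols, X.T) if np.isnan(col).all()]
    if fully_missing:
        raise ValueError(f"fully missing predictor column(s): {fully_missing}")
    out = []
    for j in range(m):
        if np.isnan(X).any():
            imp = IterativeImputer(
                sample_posterior=True, max_iter=max_iter, random_state=seed + j,
                keep_empty_features=True,
            )
            Xc = imp.fit_transform(X)
        else:
            Xc = X.copy()
        comp = table.copy()
        comp[cols] = Xc
        out.append(comp)
    return out


def _design_for_variant(
    train: pd.DataFrame, test: pd.DataFrame, variant: str, measures
) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrices for one event's train/test rows under LM1–LM3."""
    if variant not in LM_VARIANTS:
        raise ValueError(f"variant must be one of {LM_VARIANTS}")
    blocks_tr, blocks_te = [], []

    ns_last = NaturalSplineFeature(df=2).fit(train["y_last"])
    blocks_tr.append(ns_last.transform(train["y_last"]))
    blocks_te.append(ns_last.transform(test["y_last"]))
    if variant in ("LM2", "LM3"):
        ns_prev = NaturalSplineFeature(df=2).fit(train["y_prev"])
        blocks_tr.append(ns_prev.transform(train["y_prev"]))
        blocks_te.append(ns_prev.transform(test["y_prev"]))
    if variant == "LM3":
        blocks_tr.append(train[["prior_count"]].to_numpy(float))
        blocks_te.append(test[["prior_count"]].to_numpy(float))
    other_cols = [c for c in train.columns if c.startswith("recent_")]
    cov_cols = [
        c for c in train.columns
        if c not in ("event", "measure", "patient_id", "target_time", "outcome",
                     "y_last", "y_prev", "prior_count") and not c.startswith("recent_")
    ]
    blocks_tr.append(train[other_cols + cov_cols].to_numpy(float))
    blocks_te.append(test[other_cols + cov_cols].to_numpy(float))
    return np.column_stack(blocks_tr), np.column_stack(blocks_te)


def _fit_logistic(Xtr: np.ndarray, ytr: np.ndarray) -> LogisticRegression:
    """Unpenalized fit; fall back to ridge when separation breaks the MLE."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf = LogisticRegression(penalty=None, max_iter=2000)
        clf.fit(Xtr, ytr)
    if not np.all(np.isfinite(clf.coef_)) or np.abs(clf.coef_).max() > 1e4:
        warnings.warn("possible separation: refitting with L2 penalty", stacklevel=2)
        clf = LogisticRegression(penalty="l2", C=1.0, max_iter=2000)
        clf.fit(Xtr, ytr)
    return clf


def fit_logistic_suite(
    imputed_tables: list[pd.DataFrame],
    variant: str,
    folds: dict,
    measures=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-validated logistic predictions for every event.

    ``folds`` is the same patient-level fold assignment used by CVSP so
    AUC comparisons are paired.  Probabilities are averaged across
    imputed completions; one pooled ROC per event.
    """
    base = imputed_tables[0]
    events = sorted(base["event"].unique())
    fold_ids = sorted(set(folds.values()))
    prob_sum = np.zeros(len(base))
    for table in imputed_tables:
        fold_of_row = table["patient_id"].map(folds).to_numpy()
        probs = np.full(len(table), np.nan)
        for ev in events:
            ev_mask = (table["event"] == ev).to_numpy()
            for f in fold_ids:
                tr = ev_mask & (fold_of_row != f)
                te = ev_mask & (fold_of_row == f)
                if not te.any():
                    continue
                ytr = table.loc[tr, "outcome"].to_numpy()
                if len(np.unique(ytr)) < 2:
                    probs[te] = ytr.mean() if len(ytr) else 0.0
                    continue
                Xtr, Xte = _design_for_variant(table[tr], table[te], variant, measures)
                clf = _fit_logistic(Xtr, ytr)
                probs[te] = clf.predict_proba(Xte)[:, 1]
        prob_sum += probs
    out = base[["event", "measure", "patient_id", "target_time", "outcome"]].copy()
    out["prob"] = prob_sum / len(imputed_tables)

    rows = []
    for ev in events:
        sub = out[out["event"] == ev]
        y = sub["outcome"].to_numpy()
        if len(np.unique(y)) < 2:
            rows.append({"event": ev, "auc": np.nan})
            continue
        auc, lo, hi, se = delong_auc_ci(y, sub["prob"].to_numpy())
        rows.append({"event": ev, "auc": auc, "ci_low": lo, "ci_high": hi,
                     "n_instances": len(sub), "n_events": int(y.sum())})
    return out, pd.DataFrame(rows).set_index("event")


@dataclass
class RandomForestSettings:
    """Forest hyperparameters (exposed, defaults conventional)."""

    n_trees: int = 500
    max_features: str | float = "sqrt"
    seed: int = 0
    bootstrap: bool = True


def fit_random_forest(
    imputed_tables: list[pd.DataFrame],
    settings: RandomForestSettings | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random forest per event with out-of-bag probability evaluation.

    Uses the LM3 covariate set (raw values, no spline expansion).  OOB
    probabilities are averaged across imputed completions and the AUC is
    computed on them.
    """
    settings = settings or RandomForestSettings()
    if not settings.bootstrap or settings.n_trees < 2:
        raise ValueError("OOB estimates require bootstrap=True and >= 2 trees")
    base = imputed_tables[0]
    events = sorted(base["event"].unique())
    cols = _predictor_columns(base)
    prob_sum = np.zeros(len(base))
    for rep, table in enumerate(imputed_tables):
        probs = np.full(len(table), np.nan)
        for ev in events:
            sel = (table["event"] == ev).to_numpy()
            y = table.loc[sel, "outcome"].to_numpy()
            if len(np.unique(y)) < 2:
                raise ValueError(f"event {ev!r}: a class is absent")
            rf = RandomForestClassifier(
                n_estimators=settings.n_trees,
                max_features=settings.max_features,
                oob_score=True,
                bootstrap=True,
                random_state=settings.seed + rep,
                n_jobs=1,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rf.fit(table.loc[sel, cols].to_numpy(float), y)
            oob = rf.oob_decision_function_[:, list(rf.classes_).index(1.0)]
            probs[sel] = np.nan_to_num(oob, nan=y.mean())
        prob_sum += probs
    out = base[["event", "measure", "patient_id", "target_time", "outcome"]].copy()
    out["prob"] = prob_sum / len(imputed_tables)
    rows = []
    for ev in events:
        sub = out[out["event"] == ev]
        auc, lo, hi, se = delong_auc_ci(sub["outcome"].to_numpy(), sub["prob"].to_numpy())
        rows.append({"event": ev, "auc": auc, "ci_low": lo, "ci_high": hi,
                     "n_instances": len(sub), "n_events": int(sub["outcome"].sum())})
    return out, pd.DataFrame(rows).set_index("event")
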
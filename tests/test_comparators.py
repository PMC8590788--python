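"""Event-table construction, imputation, logistic suite, random forest."""

import warnings

import numpy as np
import pandas as pd
import pytest

from scleropred import SimulationSpec, simulate_cohort
from scleropred.comparators import (
    RandomForestSettings,
    build_event_table,
    fit_logistic_suite,
    fit_random_forest,
    impute_covariates,
)
from scleropred.cvsp import assign_folds
from scleropred.data_model import (
    AnalysisConfig,
    EventDefinition,
    LongitudinalDataset,
    default_events,
)


def _toy_ef_dataset():
    obs = pd.DataFrame(
        {
            "patient_id": ["A"] * 3,
            "time_years": [1.0, 2.0, 3.0],
            "measure": ["EF"] * 3,
            "value": [52.0, 48.0, 36.0],
        }
    )
    cov = pd.DataFrame(
        {
            "patient_id": ["A"],
            "age_onset": [50.0],
            "race": ["white"],
            "gender": ["female"],
            "skin_subtype": ["limited"],
            "aca": [0],
            "rnapol": [0],
            "scl70": [0],
        }
    )
    cfg = AnalysisConfig(
        measures=("EF",),
        events=[EventDefinition("EF", 50.0, "below", "mild", "EF<50", inclusive=False)],
        apply_min_obs_filter=False,
    )
    return LongitudinalDataset.from_frames(obs, cov, cfg)


def test_toy_history_prior_count_and_last_value():
    ds = _toy_ef_dataset()
    table = build_event_table(ds)
    # targets: visit 2 (value 48) and visit 3 (value 36)
    assert len(table) == 2
    last = table.sort_values("target_time").iloc[-1]
    assert last["outcome"] == 1.0  # 36 < 50
    assert last["y_last"] == 48.0
    assert last["prior_count"] == 1.0  # only the 48 was an event before visit 3
    assert last["y_prev"] == 52.0


def test_single_observation_contributes_no_rows():
    ds = _toy_ef_dataset()
    ds_single = ds.subset(["A"])
    ds_single.observations = ds_single.observations.iloc[:1].reset_index(drop=True)
    assert len(build_event_table(ds_single)) == 0


def test_missing_second_to_last_flagged_not_dropped():
    ds = _toy_ef_dataset()
    table = build_event_table(ds).sort_values("target_time")
    assert np.isnan(table.iloc[0]["y_prev"])  # only one prior value at visit 2


@pytest.fixture(scope="module")
def sim_tables():
    spec = SimulationSpec(m=60, measures=("pFVC", "pDLCO"), seed=23)
    ds, _ = simulate_cohort(spec)
    table = build_event_table(ds)
    folds = assign_folds(ds, 3, seed=4)
    return ds, table, folds


def test_no_missingness_imputation_is_identity(sim_tables):
    _, table, _ = sim_tables
    complete = table.dropna().reset_index(drop=True)
    outs = impute_covariates(complete, m=3, seed=0)
    for out in outs:
        pd.testing.assert_frame_equal(out, complete)


def test_single_imputation_warns(sim_tables):
    _, table, _ = sim_tables
    with pytest.warns(UserWarning, match="single imputation"):
        impute_covariates(table.head(50), m=1, seed=0)


def test_fully_missing_column_rejected(sim_tables):
    _, table, _ = sim_tables
    broken = table.copy()
    broken["y_prev"] = np.nan
    with pytest.raises(ValueError, match="y_prev"):
        impute_covariates(broken, m=2, seed=0)


def test_mcar_imputation_preserves_bivariate_slope(rng):
    """MCAR holes in a correlated Gaussian pair: regression slope from
    imputed data within 10% of the complete-data slope."""
    n = 2000
    x = rng.normal(size=n)
    ycol = 0.8 * x + np.sqrt(1 - 0.8**2) * rng.normal(size=n)
    table = pd.DataFrame(
        {
            "event": "e", "measure": "m", "patient_id": np.arange(n),
            "target_time": 1.0, "outcome": 0.0,
            "y_last": x, "y_prev": ycol,
        }
    )
    full_slope = np.polyfit(table["y_last"], table["y_prev"], 1)[0]
    holes = table.copy()
    mask = rng.random(n) < 0.3
    holes.loc[mask, "y_prev"] = np.nan
    outs = impute_covariates(holes, m=3, seed=1)
    slopes = [np.polyfit(o["y_last"], o["y_prev"], 1)[0] for o in outs]
    assert abs(np.mean(slopes) - full_slope) < 0.1 * abs(full_slope)


def test_training_deviance_non_increasing_lm1_to_lm3(sim_tables):
    """Nested logistic models: adding terms cannot worsen training fit."""
    from sklearn.metrics import log_loss

    from scleropred.comparators import _design_for_variant, _fit_logistic

    _, table, _ = sim_tables
    one_event = table[table["event"] == table["event"].iloc[0]]
    complete = impute_covariates(one_event.reset_index(drop=True), m=2, seed=0)[0]
    y = complete["outcome"].to_numpy()
    losses = []
    for variant in ("LM1", "LM2", "LM3"):
        Xtr, _ = _design_for_variant(complete, complete, variant, None)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf = _fit_logistic(Xtr, y)
        losses.append(log_loss(y, clf.predict_proba(Xtr)[:, 1]))
    assert losses[1] <= losses[0] + 1e-6
    assert losses[2] <= losses[1] + 1e-6


def test_separable_event_reaches_high_cv_auc(rng):
    """A cleanly separable synthetic event is almost perfectly ranked."""
    n = 600
    pid = np.arange(n)
    y_last = rng.normal(size=n)
    outcome = (y_last < -0.2).astype(float)
    table = pd.DataFrame(
        {
            "event": "sep", "measure": "m", "patient_id": pid, "target_time": 1.0,
            "outcome": outcome, "y_last": y_last, "y_prev": y_last,
            "prior_count": 0.0, "age_onset_std": rng.normal(size=n),
        }
    )
    folds = {p: p % 3 for p in pid}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, summary = fit_logistic_suite([table], "LM1", folds)
    assert summary.loc["sep", "auc"] > 0.95


def test_random_forest_null_oob_auc_near_half(rng):
    n = 5000
    table = pd.DataFrame(
        {
            "event": "null", "measure": "m", "patient_id": np.arange(n),
            "target_time": 1.0,
            "outcome": rng.binomial(1, 0.3, size=n).astype(float),
            "y_last": rng.normal(size=n), "y_prev": rng.normal(size=n),
            "prior_count": rng.poisson(1.0, size=n).astype(float),
            "age_onset_std": rng.normal(size=n),
        }
    )
    _, summary = fit_random_forest([table], RandomForestSettings(n_trees=300, seed=0))
    assert 0.45 < summary.loc["null", "auc"] < 0.55


def test_random_forest_without_bootstrap_rejected(sim_tables):
    _, table, _ = sim_tables
    with pytest.raises(ValueError, match="bootstrap"):
        fit_random_forest([table], RandomForestSettings(n_trees=1))


def test_logistic_suite_runs_end_to_end(sim_tables):
    ds, table, folds = sim_tables
    completed = impute_covariates(table, m=2, seed=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        preds, summary = fit_logistic_suite(completed, "LM3", folds)
    assert set(summary.index) == set(table["event"].unique())
    assert preds["prob"].between(0, 1).all()
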
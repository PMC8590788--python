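"""Cohort I/O, filtering rules, and event labelling."""

import numpy as np
import pandas as pd
import pytest

from scleropred.data_model import (
    AnalysisConfig,
    EventDefinition,
    LongitudinalDataset,
    SchemaError,
    ValidationError,
    default_events,
    label_events,
    read_cohort,
)


def _cov_frame(ids):
    n = len(ids)
    return pd.DataFrame(
        {
            "patient_id": ids,
            "age_onset": [50.0] * n,
            "race": ["white"] * n,
            "gender": ["female"] * n,
            "skin_subtype": ["limited"] * n,
            "aca": [0] * n,
            "rnapol": [0] * n,
            "scl70": [1] * n,
        }
    )


def _obs_frame(rows):
    return pd.DataFrame(rows, columns=["patient_id", "time_years", "measure", "value"])


@pytest.fixture()
def toy_files(tmp_path):
    obs = _obs_frame(
        [
            ("A", 1.0, "pFVC", 80.0),
            ("A", 2.0, "pFVC", 75.0),
            ("A", 1.0, "pDLCO", 70.0),
            ("A", 2.5, "pDLCO", 65.0),
            ("B", 0.5, "pFVC", 90.0),
            ("B", 1.5, "pFVC", 88.0),
            ("B", 0.5, "pDLCO", 80.0),
            ("B", 1.5, "pDLCO", 78.0),
            ("C", 3.0, "pFVC", 60.0),  # single pFVC value -> ineligible
            ("C", 3.0, "pDLCO", 55.0),
            ("C", 4.0, "pDLCO", 50.0),
        ]
    )
    cov = _cov_frame(["A", "B", "C"])
    op, cp = tmp_path / "obs.csv", tmp_path / "cov.csv"
    obs.to_csv(op, index=False)
    cov.to_csv(cp, index=False)
    return op, cp


MEASURES_2 = ("pFVC", "pDLCO")
CFG2 = AnalysisConfig(measures=MEASURES_2,
                      events=[e for e in default_events() if e.measure in MEASURES_2])


def test_min_obs_filter_drops_ineligible_patient(toy_files):
    ds = read_cohort(*toy_files, CFG2)
    assert set(ds.patient_ids) == {"A", "B"}
    assert ds.load_report.n_patients_dropped_min_obs == 1


def test_time_window_rows_dropped_and_logged(tmp_path):
    obs = _obs_frame(
        [("A", t, "pFVC", 80.0) for t in (1.0, 2.0, 45.0)]
        + [("A", t, "pDLCO", 70.0) for t in (1.0, 2.0)]
    )
    obs.to_csv(tmp_path / "o.csv", index=False)
    _cov_frame(["A"]).to_csv(tmp_path / "c.csv", index=False)
    ds = read_cohort(tmp_path / "o.csv", tmp_path / "c.csv", CFG2)
    assert ds.load_report.n_rows_outside_window == 1
    assert ds.observations["time_years"].max() <= 40.0


def test_empty_observation_file_warns_not_crashes(tmp_path):
    _obs_frame([]).to_csv(tmp_path / "o.csv", index=False)
    _cov_frame([]).to_csv(tmp_path / "c.csv", index=False)
    with pytest.warns(UserWarning, match="empty"):
        ds = read_cohort(tmp_path / "o.csv", tmp_path / "c.csv", CFG2)
    assert len(ds.observations) == 0


def test_missing_column_names_the_column(tmp_path):
    pd.DataFrame({"patient_id": [], "measure": [], "value": []}).to_csv(
        tmp_path / "o.csv", index=False
    )
    _cov_frame([]).to_csv(tmp_path / "c.csv", index=False)
    with pytest.raises(SchemaError, match="time_years"):
        read_cohort(tmp_path / "o.csv", tmp_path / "c.csv", CFG2)


def test_unknown_measure_rejected(tmp_path):
    _obs_frame([("A", 1.0, "nonsense", 5.0)]).to_csv(tmp_path / "o.csv", index=False)
    _cov_frame(["A"]).to_csv(tmp_path / "c.csv", index=False)
    with pytest.raises(ValidationError, match="nonsense"):
        read_cohort(tmp_path / "o.csv", tmp_path / "c.csv", CFG2)


def test_duplicate_rows_averaged_with_warning():
    obs = _obs_frame(
        [
            ("A", 1.0, "pFVC", 80.0),
            ("A", 1.0, "pFVC", 90.0),
            ("A", 2.0, "pFVC", 70.0),
            ("A", 1.0, "pDLCO", 60.0),
            ("A", 2.0, "pDLCO", 55.0),
        ]
    )
    with pytest.warns(UserWarning, match="duplicate"):
        ds = LongitudinalDataset.from_frames(obs, _cov_frame(["A"]), CFG2)
    merged = ds.observations.query("measure == 'pFVC' and time_years == 1.0")
    assert len(merged) == 1
    assert merged["value"].iloc[0] == pytest.approx(85.0)


def test_round_trip_write_read_identical(toy_files, tmp_path):
    ds = read_cohort(*toy_files, CFG2)
    ds.write(tmp_path / "o2.csv", tmp_path / "c2.csv")
    ds2 = read_cohort(tmp_path / "o2.csv", tmp_path / "c2.csv", CFG2)
    pd.testing.assert_frame_equal(ds.observations, ds2.observations)
    pd.testing.assert_frame_equal(ds.covariates, ds2.covariates)


def test_observed_patient_without_covariates_rejected():
    obs = _obs_frame([("A", 1.0, "pFVC", 80.0), ("A", 2.0, "pFVC", 75.0),
                      ("A", 1.0, "pDLCO", 60.0), ("A", 2.0, "pDLCO", 55.0)])
    with pytest.raises(ValidationError, match="covariate"):
        LongitudinalDataset.from_frames(obs, _cov_frame(["B"]), CFG2)


@pytest.mark.parametrize(
    "measure,value,label,expected",
    [
        ("EF", 35.0, "EF<35", 0.0),  # strict inequality at the threshold
        ("EF", 34.99, "EF<35", 1.0),
        ("EF", 50.0, "EF<50", 0.0),
        ("pFVC", 70.0, "pFVC<=70", 1.0),  # inclusive
        ("pFVC", 70.01, "pFVC<=70", 0.0),
        ("RVSP", 44.9, "RVSP>=45", 0.0),
        ("RVSP", 45.0, "RVSP>=45", 1.0),
    ],
)
def test_event_operators_at_thresholds(measure, value, label, expected):
    ev = {e.label: e for e in default_events()}[label]
    assert ev.measure == measure
    assert ev.indicator(np.array([value]))[0] == expected


def test_severe_event_implies_mild_event(small_cohort):
    ds, _ = small_cohort
    labels = label_events(ds)
    for measure, mild, severe in [("pFVC", "pFVC<=70", "pFVC<=60")]:
        sel = ds.observations["measure"] == measure
        assert (labels.loc[sel, severe] <= labels.loc[sel, mild]).all()


def test_event_on_unobserved_measure_rejected(small_cohort):
    ds, _ = small_cohort
    bad = ds.events + [EventDefinition("RVSP", 45.0, "above", "mild", "RVSP>=45")]
    ds2 = LongitudinalDataset(ds.observations, ds.covariates, ds.measures, bad)
    with pytest.raises(ValidationError):
        label_events(ds2)


def test_config_round_trip_from_yaml(tmp_path):
    cfg_text = """
measures: [pFVC, pDLCO]
time_window: [0, 40]
min_obs_per_measure: 2
events:
  - {measure: pFVC, threshold: 70, direction: below, severity: mild, label: "pFVC<=70"}
"""
    path = tmp_path / "cfg.yaml"
    path.write_text(cfg_text)
    cfg = AnalysisConfig.from_file(path)
    assert cfg.measures == ("pFVC", "pDLCO")
    assert cfg.events[0].threshold == 70.0
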
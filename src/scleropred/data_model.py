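"""Cohort representation, clinical event definitions, and file I/O.

Longitudinal biomarker data are held in long format: one row per
(patient, time, measure) with the value on the original clinical scale.
Time is fractional years since disease onset; calendar-date arithmetic is
done upstream and is out of scope here.  Clinical events are threshold
crossings of individual biomarkers (e.g. ejection fraction dropping below
50% signals cardiomyopathy), possibly recurring within a patient.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SchemaError",
    "ValidationError",
    "EventDefinition",
    "AnalysisConfig",
    "LoadReport",
    "LongitudinalDataset",
    "DEFAULT_MEASURES",
    "CATEGORY_LEVELS",
    "COVARIATE_COLUMNS",
    "default_events",
    "read_cohort",
    "label_events",
]

#: Canonical measure ordering: two pulmonary, two cardiac biomarkers.
DEFAULT_MEASURES = ("pFVC", "pDLCO", "EF", "RVSP")

#: Declared category dictionaries; the first level is the reference.
CATEGORY_LEVELS = {
    "race": ("white", "black", "other"),
    "gender": ("female", "male"),
    "skin_subtype": ("limited", "diffuse"),
}

COVARIATE_COLUMNS = (
    "age_onset",
    "race",
    "gender",
    "skin_subtype",
    "aca",
    "rnapol",
    "scl70",
)

OBS_COLUMNS = ("patient_id", "time_years", "measure", "value")


class SchemaError(ValueError):
    """A required column is absent from an input table."""


class ValidationError(ValueError):
    """Input values violate a dataset invariant."""


@dataclass(frozen=True)
class EventDefinition:
    """A clinical event defined by a biomarker threshold crossing.

    ``direction`` is "below" when low values are pathological (EF, pFVC)
    and "above" when high values are (RVSP).  ``inclusive`` fixes the
    comparison operator used when labelling observed data at the exact
    threshold; for model-based probabilities of a continuous variable the
    distinction is immaterial.
    """

    measure: str
    threshold: float
    direction: str  # "below" | "above"
    severity: str  # "mild" | "severe"
    label: str
    inclusive: bool = True

    def __post_init__(self) -> None:
        if self.direction not in ("below", "above"):
            raise ValidationError(f"direction must be below/above, got {self.direction!r}")
        if self.severity not in ("mild", "severe"):
            raise ValidationError(f"severity must be mild/severe, got {self.severity!r}")

    def indicator(self, values: np.ndarray) -> np.ndarray:
        """Binary event indicator for clinical-scale values."""
        v = np.asarray(values, dtype=float)
        if self.direction == "below":
            return (v <= self.threshold if self.inclusive else v < self.threshold).astype(float)
        return (v >= self.threshold if self.inclusive else v > self.threshold).astype(float)


def default_events() -> list[EventDefinition]:
    """The six standard mild/severe event definitions.

    EF uses strict inequalities (EF < 50, EF < 35); pFVC and RVSP use
    inclusive ones (pFVC <= 70/60, RVSP >= 45/50).
    """
    return [
        EventDefinition("EF", 50.0, "below", "mild", "EF<50", inclusive=False),
        EventDefinition("EF", 35.0, "below", "severe", "EF<35", inclusive=False),
        EventDefinition("pFVC", 70.0, "below", "mild", "pFVC<=70", inclusive=True),
        EventDefinition("pFVC", 60.0, "below", "severe", "pFVC<=60", inclusive=True),
        EventDefinition("RVSP", 45.0, "above", "mild", "RVSP>=45", inclusive=True),
        EventDefinition("RVSP", 50.0, "above", "severe", "RVSP>=50", inclusive=True),
    ]


@dataclass
class AnalysisConfig:
    """Analysis settings shared across the pipeline."""

    measures: tuple[str, ...] = DEFAULT_MEASURES
    events: list[EventDefinition] = field(default_factory=default_events)
    time_window: tuple[float, float] = (0.0, 40.0)
    min_obs_per_measure: int = 2
    apply_min_obs_filter: bool = True
    visit_tolerance: float = 1.0 / 365.25  # years; same-day values form one visit

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) if path.suffix in (".yml", ".yaml") else json.load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "AnalysisConfig":
        kwargs: dict = {}
        if "measures" in raw:
            kwargs["measures"] = tuple(raw["measures"])
        if "events" in raw:
            kwargs["events"] = [
                EventDefinition(
                    measure=e["measure"],
                    threshold=float(e["threshold"]),
                    direction=e["direction"],
                    severity=e["severity"],
                    label=e.get("label", f"{e['measure']}@{e['threshold']}"),
                    inclusive=bool(e.get("inclusive", True)),
                )
                for e in raw["events"]
            ]
        for key in ("min_obs_per_measure", "apply_min_obs_filter", "visit_tolerance"):
            if key in raw:
                kwargs[key] = raw[key]
        if "time_window" in raw:
            kwargs["time_window"] = tuple(float(v) for v in raw["time_window"])
        return cls(**kwargs)


@dataclass
class LoadReport:
    """Row/patient accounting from :func:`read_cohort`."""

    n_rows_input: int = 0
    n_rows_outside_window: int = 0
    n_rows_duplicated: int = 0
    n_rows_kept: int = 0
    n_patients_input: int = 0
    n_patients_dropped_min_obs: int = 0
    n_patients_kept: int = 0

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"rows: {self.n_rows_input} in, {self.n_rows_outside_window} outside window, "
            f"{self.n_rows_duplicated} duplicate-merged, {self.n_rows_kept} kept; "
            f"patients: {self.n_patients_input} in, "
            f"{self.n_patients_dropped_min_obs} dropped (<min obs/measure), "
            f"{self.n_patients_kept} kept"
        )


@dataclass
class LongitudinalDataset:
    """Long-format biomarker observations plus baseline covariates.

    ``observations`` has columns ``patient_id, time_years, measure, value``
    sorted by (patient, time, measure); ``covariates`` has one row per
    patient (indexed by ``patient_id``).
    """

    observations: pd.DataFrame
    covariates: pd.DataFrame
    measures: tuple[str, ...] = DEFAULT_MEASURES
    events: list[EventDefinition] = field(default_factory=default_events)
    load_report: LoadReport | None = None

    # ------------------------------------------------------------------
    @classmethod
    def from_frames(
        cls,
        observations: pd.DataFrame,
        covariates: pd.DataFrame,
        config: AnalysisConfig | None = None,
    ) -> "LongitudinalDataset":
        """Validate, deduplicate and filter raw frames into a dataset."""
        cfg = config or AnalysisConfig()
        report = LoadReport()

        obs = observations.copy()
        for col in OBS_COLUMNS:
            if col not in obs.columns:
                raise SchemaError(f"observations table is missing column {col!r}")
        for col in ("patient_id",) + tuple(COVARIATE_COLUMNS):
            if col not in covariates.columns:
                raise SchemaError(f"covariates table is missing column {col!r}")

        obs = obs.loc[:, list(OBS_COLUMNS)]
        obs["time_years"] = obs["time_years"].astype(float)
        obs["value"] = obs["value"].astype(float)
        report.n_rows_input = len(obs)
        report.n_patients_input = obs["patient_id"].nunique()

        if len(obs) == 0:
            warnings.warn("empty observation table", stacklevel=2)

        unknown = set(obs["measure"].unique()) - set(cfg.measures)
        if unknown:
            raise ValidationError(f"unknown measure name(s): {sorted(unknown)}")

        lo, hi = cfg.time_window
        in_window = (obs["time_years"] >= lo) & (obs["time_years"] <= hi)
        report.n_rows_outside_window = int((~in_window).sum())
        obs = obs.loc[in_window]

        # Duplicate (patient, time, measure) rows: keep the mean, warn.
        key = ["patient_id", "time_years", "measure"]
        n_before = len(obs)
        if obs.duplicated(key).any():
            obs = obs.groupby(key, as_index=False, sort=False)["value"].mean()
            report.n_rows_duplicated = n_before - len(obs)
            warnings.warn(
                f"{report.n_rows_duplicated} duplicate (patient, time, measure) "
                "rows merged by averaging",
                stacklevel=2,
            )

        if cfg.apply_min_obs_filter and len(obs) > 0:
            counts = (
                obs.groupby(["patient_id", "measure"]).size().unstack(fill_value=0)
            )
            for m in cfg.measures:
                if m not in counts.columns:
                    counts[m] = 0
            eligible = counts.loc[:, list(cfg.measures)].min(axis=1) >= cfg.min_obs_per_measure
            keep_ids = set(counts.index[eligible])
            report.n_patients_dropped_min_obs = int((~eligible).sum())
            obs = obs[obs["patient_id"].isin(keep_ids)]

        obs = obs.sort_values(["patient_id", "time_years", "measure"], kind="mergesort")
        obs = obs.reset_index(drop=True)
        report.n_rows_kept = len(obs)
        report.n_patients_kept = obs["patient_id"].nunique()

        cov = covariates.copy()
        if cov["patient_id"].duplicated().any():
            raise ValidationError("covariates table has duplicate patient_id rows")
        cov = cov.set_index("patient_id", drop=True)
        missing_cov = set(obs["patient_id"].unique()) - set(cov.index)
        if missing_cov:
            raise ValidationError(
                f"patients without a covariate row: {sorted(missing_cov)[:5]} ..."
            )
        for col, levels in CATEGORY_LEVELS.items():
            bad = set(cov[col].dropna().unique()) - set(levels)
            if bad:
                raise ValidationError(f"unknown {col} level(s): {sorted(bad)}")
        cov = cov.loc[sorted(set(obs["patient_id"]))] if len(obs) else cov.iloc[:0]

        for ev in cfg.events:
            if ev.measure not in cfg.measures:
                raise ValidationError(
                    f"event {ev.label!r} references unobserved measure {ev.measure!r}"
                )

        return cls(
            observations=obs,
            covariates=cov,
            measures=tuple(cfg.measures),
            events=list(cfg.events),
            load_report=report,
        )

    # ------------------------------------------------------------------
    @property
    def patient_ids(self) -> list:
        return list(self.covariates.index)

    @property
    def n_patients(self) -> int:
        return len(self.covariates)

    def patient_observations(self, patient_id) -> pd.DataFrame:
        return self.observations[self.observations["patient_id"] == patient_id]

    def subset(self, patient_ids: Iterable) -> "LongitudinalDataset":
        """Restrict to a set of patients (no refiltering)."""
        ids = set(patient_ids)
        obs = self.observations[self.observations["patient_id"].isin(ids)].reset_index(drop=True)
        cov = self.covariates.loc[[p for p in self.covariates.index if p in ids]]
        return replace(self, observations=obs, covariates=cov, load_report=None)

    def with_values(self, values: np.ndarray) -> "LongitudinalDataset":
        """Return a copy whose observation values are replaced (e.g. z scale)."""
        obs = self.observations.copy()
        obs["value"] = np.asarray(values, dtype=float)
        return replace(self, observations=obs, load_report=None)

    def write(self, obs_path: str | Path, cov_path: str | Path) -> None:
        self.observations.to_csv(obs_path, index=False)
        self.covariates.reset_index().to_csv(cov_path, index=False)


def read_cohort(
    observations_path: str | Path,
    covariates_path: str | Path,
    config: AnalysisConfig | str | Path | None = None,
) -> LongitudinalDataset:
    """Read a cohort from CSV files, applying window and eligibility filters.

    The time window restricts observations to the configured span of years
    since onset (default [0, 40]); the eligibility rule keeps patients with
    at least ``min_obs_per_measure`` observations of every configured
    measure.  A :class:`LoadReport` with kept/dropped counts is attached to
    the returned dataset.
    """
    if config is not None and not isinstance(config, AnalysisConfig):
        config = AnalysisConfig.from_file(config)
    obs = pd.read_csv(observations_path)
    cov = pd.read_csv(covariates_path)
    return LongitudinalDataset.from_frames(obs, cov, config)


def label_events(ds: LongitudinalDataset) -> pd.DataFrame:
    """Per-observation binary indicators for each event definition.

    Returns a frame aligned row-for-row with ``ds.observations`` with one
    column per event label; entries are 0/1 for rows of the event's
    measure and NaN for rows of other measures.
    """
    out = {}
    for ev in ds.events:
        if ev.measure not in ds.measures:
            raise ValidationError(f"event {ev.label!r} on unobserved measure {ev.measure!r}")
        col = np.full(len(ds.observations), np.nan)
        sel = (ds.observations["measure"] == ev.measure).to_numpy()
        col[sel] = ev.indicator(ds.observations.loc[sel, "value"].to_numpy())
        out[ev.label] = col
    return pd.DataFrame(out, index=ds.observations.index)
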
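"""Fixed- and random-effect design matrices for the multivariate model.

The population time trend for every measure is a natural cubic spline of
years since onset with 3 degrees of freedom, internal knots at 10 and 30
years and boundary knots at 0 and 40 years.  Baseline covariates (age of
onset, race, gender, skin subtype, three autoantibodies) enter every
measure's block with measure-specific coefficients.

Patient-specific random effects use, per measure, an intercept, a linear
slope, and two linear-spline (hinge) deviations with knots placed 10 and
3 years before the patient's most recent observation (the "anchor").
Anchoring the hinges at the end of follow-up keeps early observations
from dominating the predicted recent trend; knots falling before onset
are floored at time 0.

Stacked per patient, the fixed and random designs are block diagonal by
measure (measure-major row order), matching the stacked response
Y_i = (Y_i1', ..., Y_iK')'.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

from .data_model import (
    CATEGORY_LEVELS,
    COVARIATE_COLUMNS,
    LongitudinalDataset,
    ValidationError,
)

__all__ = [
    "natural_spline_basis",
    "NaturalSplineFeature",
    "random_effect_basis",
    "CovariateEncoder",
    "FixedSpec",
    "RandomSpec",
    "PatientDesign",
    "DesignBundle",
    "build_design_bundle",
    "group_visits",
]

#: Fixed standardization for age of onset (years); keeps the encoding
#: deterministic so simulated truth coefficients are directly comparable.
AGE_CENTER = 45.0
AGE_SCALE = 13.0


# ----------------------------------------------------------------------
# Natural cubic splines (same construction as the classic regression
# spline basis: cubic B-splines projected onto the subspace with zero
# second derivative at the boundary knots).
# ----------------------------------------------------------------------
def _bspline_design(x: np.ndarray, aug_knots: np.ndarray, deriv: int = 0) -> np.ndarray:
    """Cubic B-spline design matrix (columns = len(aug_knots) - 4)."""
    ncol = len(aug_knots) - 4
    out = np.empty((len(x), ncol))
    for j in range(ncol):
        coef = np.zeros(ncol)
        coef[j] = 1.0
        sp = BSpline(aug_knots, coef, 3, extrapolate=False)
        if deriv:
            sp = sp.derivative(deriv)
        out[:, j] = sp(x)
    return np.nan_to_num(out)


def natural_spline_basis(
    times,
    df: int = 3,
    internal_knots=(10.0, 30.0),
    boundary_knots=(0.0, 40.0),
    warn_outside: bool = True,
) -> np.ndarray:
    """Natural cubic spline basis without intercept (``df`` columns).

    ``df`` must equal ``len(internal_knots) + 1``.  The function is linear
    beyond the boundary knots (natural constraint); times outside the
    boundary are evaluated by linear extrapolation with a warning.
    """
    x = np.asarray(times, dtype=float)
    internal_knots = tuple(float(k) for k in internal_knots)
    b0, b1 = (float(b) for b in boundary_knots)
    if not all(b0 < k < b1 for k in internal_knots):
        raise ValueError("boundary knots must bracket the internal knots")
    if df != len(internal_knots) + 1:
        raise ValueError(
            f"df={df} inconsistent with {len(internal_knots)} internal knots "
            "(need df = n_internal + 1)"
        )
    aug = np.sort(np.r_[[b0] * 4, internal_knots, [b1] * 4])

    outside_lo = x < b0
    outside_hi = x > b1
    if warn_outside and (outside_lo.any() or outside_hi.any()):
        warnings.warn(
            "times outside the boundary knots: using linear extrapolation",
            stacklevel=2,
        )
    inside = ~(outside_lo | outside_hi)
    basis = np.zeros((len(x), len(aug) - 4))
    basis[inside] = _bspline_design(x[inside], aug)
    # linear (first-order Taylor) extension beyond the boundary knots
    for mask, b in ((outside_lo, b0), (outside_hi, b1)):
        if mask.any():
            f = _bspline_design(np.array([b]), aug)
            d = _bspline_design(np.array([b]), aug, deriv=1)
            basis[mask] = f + (x[mask, None] - b) * d

    # natural constraint: zero 2nd derivative at both boundary knots
    const = _bspline_design(np.array([b0, b1]), aug, deriv=2)
    # drop the intercept column before projecting, as in the standard basis
    basis = basis[:, 1:]
    const = const[:, 1:]
    q, _ = np.linalg.qr(const.T, mode="complete")
    return basis @ q[:, 2:]


class NaturalSplineFeature:
    """Data-driven natural spline expansion ns(y, df) for scalar predictors.

    Internal knots at equally spaced quantiles of the training values,
    boundary knots at configurable quantiles (default 5th/95th
    percentiles), frozen at fit time.
    """

    def __init__(self, df: int = 2, boundary_quantiles=(0.05, 0.95)):
        self.df = df
        self.boundary_quantiles = boundary_quantiles

    def fit(self, values) -> "NaturalSplineFeature":
        v = np.asarray(values, dtype=float)
        v = v[~np.isnan(v)]
        lo, hi = np.quantile(v, self.boundary_quantiles)
        if hi <= lo:
            raise ValueError("degenerate predictor: boundary quantiles coincide")
        inner_q = np.linspace(0, 1, self.df + 1)[1:-1]
        knots = np.quantile(v[(v > lo) & (v < hi)], inner_q)
        knots = np.clip(knots, lo + 1e-9 * (hi - lo), hi - 1e-9 * (hi - lo))
        self.boundary_ = (float(lo), float(hi))
        self.knots_ = tuple(float(k) for k in knots)
        return self

    def transform(self, values) -> np.ndarray:
        return natural_spline_basis(
            np.asarray(values, dtype=float),
            df=self.df,
            internal_knots=self.knots_,
            boundary_knots=self.boundary_,
            warn_outside=False,
        )


# ----------------------------------------------------------------------
def random_effect_basis(times, anchor: float) -> np.ndarray:
    """Per-measure random-effect design: [1, t, (t-(a-10))_+, (t-(a-3))_+].

    ``anchor`` is the patient's most recent observation time; hinge knots
    that would fall before onset are floored at 0.
    """
    if anchor < 0:
        raise ValueError("anchor must be non-negative")
    t = np.asarray(times, dtype=float)
    k10 = max(anchor - 10.0, 0.0)
    k3 = max(anchor - 3.0, 0.0)
    return np.column_stack(
        [np.ones_like(t), t, np.maximum(t - k10, 0.0), np.maximum(t - k3, 0.0)]
    )


# ----------------------------------------------------------------------
class CovariateEncoder:
    """Reference-level dummy coding of the common baseline covariates.

    Category dictionaries are fixed package-wide (see
    :data:`scleropred.data_model.CATEGORY_LEVELS`); age of onset is
    standardized with fixed constants so the encoding does not depend on
    the training sample.  Unseen category levels raise.
    """

    def __init__(self) -> None:
        names = ["intercept", "age_onset_std"]
        for col, levels in CATEGORY_LEVELS.items():
            names += [f"{col}_{lv}" for lv in levels[1:]]
        names += ["aca", "rnapol", "scl70"]
        self.column_names = names

    @property
    def n_columns(self) -> int:
        return len(self.column_names)

    def encode(self, covariate_rows) -> np.ndarray:
        """(n_patients x p_cov) design from a covariates frame slice."""
        cov = covariate_rows
        n = len(cov)
        cols = [np.ones(n), (cov["age_onset"].to_numpy(float) - AGE_CENTER) / AGE_SCALE]
        for col, levels in CATEGORY_LEVELS.items():
            vals = cov[col].to_numpy()
            bad = set(vals) - set(levels)
            if bad:
                raise ValidationError(f"unseen {col} level(s) at encoding time: {sorted(bad)}")
            for lv in levels[1:]:
                cols.append((vals == lv).astype(float))
        for col in ("aca", "rnapol", "scl70"):
            cols.append(cov[col].to_numpy(float))
        out = np.column_stack(cols)
        if np.isnan(out).any():
            raise ValidationError("missing covariate values cannot be encoded; impute first")
        return out


# ----------------------------------------------------------------------
@dataclass
class FixedSpec:
    """Fixed-effect specification, identical basis for every measure."""

    spline_df: int = 3
    internal_knots: tuple[float, ...] = (10.0, 30.0)
    boundary_knots: tuple[float, float] = (0.0, 40.0)
    include_covariates: bool = True

    def spline(self, times) -> np.ndarray:
        return natural_spline_basis(
            times,
            df=self.spline_df,
            internal_knots=self.internal_knots,
            boundary_knots=self.boundary_knots,
            warn_outside=False,
        )


@dataclass
class RandomSpec:
    """Random-effect specification: intercept, slope, two anchored hinges.

    ``slope`` and ``hinge_offsets`` can be reduced (e.g. intercept-only)
    for oracle comparisons and sensitivity analyses; the default is the
    full q = 4 basis.
    """

    slope: bool = True
    hinge_offsets: tuple[float, ...] = (10.0, 3.0)

    @property
    def q(self) -> int:
        return 1 + int(self.slope) + len(self.hinge_offsets)

    def basis(self, times, anchor: float) -> np.ndarray:
        if self.slope and tuple(self.hinge_offsets) == (10.0, 3.0):
            return random_effect_basis(times, anchor)
        t = np.asarray(times, dtype=float)
        cols = [np.ones_like(t)]
        if self.slope:
            cols.append(t)
        for off in self.hinge_offsets:
            cols.append(np.maximum(t - max(anchor - off, 0.0), 0.0))
        return np.column_stack(cols)


# ----------------------------------------------------------------------
def group_visits(times: np.ndarray, tolerance: float) -> np.ndarray:
    """Assign sorted observation times to visit indices.

    Times within ``tolerance`` of the first time of the current group
    share a visit (same-day measurements of different biomarkers).
    ``times`` must be sorted ascending.
    """
    times = np.asarray(times, dtype=float)
    if len(times) == 0:
        return np.empty(0, dtype=int)
    vid = np.empty(len(times), dtype=int)
    current, start = 0, times[0]
    for i, t in enumerate(times):
        if t - start > tolerance:
            current += 1
            start = t
        vid[i] = current
    return vid


@dataclass
class PatientDesign:
    """Per-patient compact design: one row per visit, responses (V x K).

    ``Y`` holds NaN where a measure was not observed at a visit;
    ``mask`` marks observed cells.  ``U`` and ``W`` are the shared
    per-visit fixed and random design rows (identical across measures,
    block-replicated when materialized).
    """

    patient_id: object
    times: np.ndarray  # (V,) visit times
    U: np.ndarray  # (V, p) fixed design rows
    W: np.ndarray  # (V, q) random design rows
    Y: np.ndarray  # (V, K) responses, NaN = missing
    mask: np.ndarray  # (V, K) bool
    anchor: float

    @property
    def n_visits(self) -> int:
        return len(self.times)

    @property
    def n_obs(self) -> int:
        return int(self.mask.sum())

    def stacked(self):
        """Materialize measure-major stacked (y, X, Z, visit_ids, measure_ids).

        X is (n_i x K p) and Z is (n_i x K q), block diagonal by measure
        with zeros outside each measure's block; rows are grouped by
        measure (k-major) and ordered by time within measure.
        """
        V, K = self.Y.shape
        p, q = self.U.shape[1], self.W.shape[1]
        rows = [(k, v) for k in range(K) for v in range(V) if self.mask[v, k]]
        n = len(rows)
        X = np.zeros((n, K * p))
        Z = np.zeros((n, K * q))
        y = np.empty(n)
        visit_ids = np.empty(n, dtype=int)
        measure_ids = np.empty(n, dtype=int)
        for r, (k, v) in enumerate(rows):
            X[r, k * p : (k + 1) * p] = self.U[v]
            Z[r, k * q : (k + 1) * q] = self.W[v]
            y[r] = self.Y[v, k]
            visit_ids[r] = v
            measure_ids[r] = k
        return y, X, Z, visit_ids, measure_ids

    def target_design(self, target_time: float, fixed: "FixedSpec", random: "RandomSpec",
                      cov_row: np.ndarray):
        """Block-diagonal designs for the K-vector at a future time."""
        K = self.Y.shape[1]
        u = _fixed_row(np.asarray([target_time]), fixed, cov_row)[0]
        w = random.basis(np.asarray([target_time]), self.anchor)[0]
        p, q = len(u), len(w)
        Xp = np.zeros((K, K * p))
        Zp = np.zeros((K, K * q))
        for k in range(K):
            Xp[k, k * p : (k + 1) * p] = u
            Zp[k, k * q : (k + 1) * q] = w
        return Xp, Zp


def _fixed_row(times: np.ndarray, fixed: FixedSpec, cov_row: np.ndarray) -> np.ndarray:
    """Fixed design rows at given times for one patient's encoded covariates."""
    spl = fixed.spline(times)
    if fixed.include_covariates:
        return np.column_stack([np.tile(cov_row, (len(times), 1)), spl])
    return np.column_stack([np.ones((len(times), 1)), spl])


@dataclass
class DesignBundle:
    """All per-patient designs plus the shared specification."""

    patients: list[PatientDesign]
    measures: tuple[str, ...]
    fixed: FixedSpec
    random: RandomSpec
    encoder: CovariateEncoder
    p: int
    q: int
    fixed_names: list[str] = field(default_factory=list)

    @property
    def K(self) -> int:
        return len(self.measures)

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def patient(self, patient_id) -> PatientDesign:
        for pd_ in self.patients:
            if pd_.patient_id == patient_id:
                return pd_
        raise KeyError(f"patient {patient_id!r} not in bundle")


def patient_design_from_obs(
    times,
    measures_observed,
    values,
    measures: tuple[str, ...],
    fixed: FixedSpec,
    random: RandomSpec,
    cov_row: np.ndarray,
    visit_tolerance: float = 1.0 / 365.25,
    anchor: float | None = None,
    patient_id=None,
) -> PatientDesign:
    """Build a :class:`PatientDesign` from raw per-observation arrays.

    Used for prediction-time histories of patients that were not in the
    training bundle.  ``anchor`` defaults to the latest observation time
    (0 for an empty history).
    """
    t = np.asarray(times, dtype=float)
    meas = np.asarray(measures_observed)
    vals = np.asarray(values, dtype=float)
    order = np.argsort(t, kind="mergesort")
    t, meas, vals = t[order], meas[order], vals[order]
    mindex = {m: k for k, m in enumerate(measures)}
    K = len(measures)
    vid = group_visits(t, visit_tolerance)
    V = vid[-1] + 1 if len(vid) else 0
    vt = np.array([t[vid == v].mean() for v in range(V)])
    Y = np.full((V, K), np.nan)
    for tt, m, val, v in zip(t, meas, vals, vid):
        k = mindex[m]
        Y[v, k] = val if np.isnan(Y[v, k]) else 0.5 * (Y[v, k] + val)
    mask = ~np.isnan(Y)
    if anchor is None:
        anchor = float(vt[-1]) if V else 0.0
    U = _fixed_row(vt, fixed, cov_row) if V else np.empty((0, len(cov_row) + fixed.spline_df))
    W = random.basis(vt, anchor) if V else np.empty((0, random.q))
    return PatientDesign(patient_id, vt, U, W, Y, mask, anchor)


def build_design_bundle(
    ds: LongitudinalDataset,
    fixed: FixedSpec | None = None,
    random: RandomSpec | None = None,
    visit_tolerance: float = 1.0 / 365.25,
) -> DesignBundle:
    """Assemble per-patient design matrices from a (z-scale) dataset.

    Observations of different measures within ``visit_tolerance`` years
    form one visit; the visit time is the mean of the grouped times.  The
    random-effect anchor is the patient's most recent observation time.
    """
    fixed = fixed or FixedSpec()
    random = random or RandomSpec()
    encoder = CovariateEncoder()
    K = len(ds.measures)
    mindex = {m: k for k, m in enumerate(ds.measures)}

    cov_design = encoder.encode(ds.covariates) if fixed.include_covariates else None
    p = (encoder.n_columns if fixed.include_covariates else 1) + fixed.spline_df
    names = (
        (encoder.column_names if fixed.include_covariates else ["intercept"])
        + [f"ns_time_{j+1}" for j in range(fixed.spline_df)]
    )

    patients = []
    obs = ds.observations
    for idx, pid in enumerate(ds.patient_ids):
        sub = obs[obs["patient_id"] == pid]
        t = sub["time_years"].to_numpy()
        order = np.argsort(t, kind="mergesort")
        t = t[order]
        meas = sub["measure"].to_numpy()[order]
        vals = sub["value"].to_numpy()[order]
        vid = group_visits(t, visit_tolerance)
        V = vid[-1] + 1 if len(vid) else 0
        vt = np.array([t[vid == v].mean() for v in range(V)])
        Y = np.full((V, K), np.nan)
        for tt, m, val, v in zip(t, meas, vals, vid):
            k = mindex[m]
            if np.isnan(Y[v, k]):
                Y[v, k] = val
            else:  # same measure twice within one visit window: average
                Y[v, k] = 0.5 * (Y[v, k] + val)
        mask = ~np.isnan(Y)
        anchor = float(vt[-1]) if V else 0.0
        cov_row = cov_design[idx] if fixed.include_covariates else np.ones(1)
        U = _fixed_row(vt, fixed, cov_row)
        W = random.basis(vt, anchor)
        patients.append(PatientDesign(pid, vt, U, W, Y, mask, anchor))

    return DesignBundle(patients, tuple(ds.measures), fixed, random, encoder, p,
                        random.q, names)
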
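"""Synthetic cohorts with the statistical structure the model assumes.

The generator realizes the model's own data-generating process on the
latent Gaussian (z) scale — population spline trends plus covariate
effects, patient random effects b_i ~ N(0, D) on the anchored
intercept/slope/hinge basis, and within-visit residual K-vectors
~ N(0, Sigma_e) — then warps each measure through a strictly increasing
map to a clinical-like scale with skewed, non-Gaussian marginals (EF
left-skewed, RVSP right-skewed), which is what quantile normalization
must undo.  Visit times are irregular: exponential gaps (mean one year)
over up to 40 years, 5–15 visits per patient, with each measure
independently skipped at a visit with fixed probability.

Defaults mimic the shape of a scleroderma registry cohort: four
measures, the two pulmonary ones tightly correlated, substantial
between-patient heterogeneity (random-intercept SD twice the residual
SD).  A truth record (beta, D, Sigma_e, b_i, latent z values, event
indicators) accompanies every cohort so tests can compare estimates and
predictions against the generative truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import (
    DEFAULT_MEASURES,
    AnalysisConfig,
    EventDefinition,
    LongitudinalDataset,
    default_events,
)
from .design import CovariateEncoder, FixedSpec, RandomSpec

__all__ = [
    "Warp",
    "SimulationSpec",
    "CohortTruth",
    "simulate_cohort",
    "truth_event_rates",
    "default_warps",
    "default_beta",
    "default_D",
    "default_Sigma_e",
]


@dataclass(frozen=True)
class Warp:
    """Strictly increasing map from the latent z scale to a clinical scale.

    kinds: ``identity``; ``affine`` v = loc + scale*z; ``exp`` (right
    skew) v = loc + scale*exp(rate*z); ``neg_exp`` (left skew)
    v = loc - scale*exp(-rate*z).
    """

    kind: str = "identity"
    loc: float = 0.0
    scale: float = 1.0
    rate: float = 0.5

    def forward(self, z):
        z = np.asarray(z, dtype=float)
        if self.kind == "identity":
            return z.copy()
        if self.kind == "affine":
            return self.loc + self.scale * z
        if self.kind == "exp":
            return self.loc + self.scale * np.exp(self.rate * z)
        if self.kind == "neg_exp":
            return self.loc - self.scale * np.exp(-self.rate * z)
        raise ValueError(f"unknown warp kind {self.kind!r}")

    def inverse(self, v):
        v = np.asarray(v, dtype=float)
        if self.kind == "identity":
            return v.copy()
        if self.kind == "affine":
            return (v - self.loc) / self.scale
        if self.kind == "exp":
            return np.log((v - self.loc) / self.scale) / self.rate
        if self.kind == "neg_exp":
            return -np.log((self.loc - v) / self.scale) / self.rate
        raise ValueError(f"unknown warp kind {self.kind!r}")


def default_warps(measures=DEFAULT_MEASURES) -> dict[str, Warp]:
    """Clinical-like marginal scales for the four standard biomarkers."""
    table = {
        "pFVC": Warp("affine", loc=82.0, scale=15.0),
        "pDLCO": Warp("affine", loc=75.0, scale=16.0),
        "EF": Warp("neg_exp", loc=72.0, scale=14.0, rate=0.45),
        "RVSP": Warp("exp", loc=22.0, scale=9.0, rate=0.5),
    }
    return {m: table.get(m, Warp("identity")) for m in measures}


# ----------------------------------------------------------------------
# Default truths (z scale)
# ----------------------------------------------------------------------
def _measure_correlation(K: int) -> np.ndarray:
    """Cross-measure correlation: lung pair 0.7, cardiac pair 0.4, 0.2 across."""
    R = np.full((K, K), 0.2)
    np.fill_diagonal(R, 1.0)
    if K >= 2:
        R[0, 1] = R[1, 0] = 0.7
    if K >= 4:
        R[2, 3] = R[3, 2] = 0.4
    return R


def default_D(K: int, component_sds=(1.0, 0.05, 0.08, 0.12)) -> np.ndarray:
    """Random-effect covariance: Kronecker of a measure correlation matrix
    with a diagonal of per-component variances (intercept, slope, 10-yr
    hinge, 3-yr hinge)."""
    s = np.asarray(component_sds, dtype=float)
    return np.kron(_measure_correlation(K), np.diag(s**2))


def default_Sigma_e(K: int, sd: float = 0.5) -> np.ndarray:
    """Within-visit residual covariance: SD 0.5, lung residuals corr 0.5,
    cardiac 0.25, 0.15 across."""
    R = np.full((K, K), 0.15)
    np.fill_diagonal(R, 1.0)
    if K >= 2:
        R[0, 1] = R[1, 0] = 0.5
    if K >= 4:
        R[2, 3] = R[3, 2] = 0.25
    return R * sd**2


def default_beta(measures=DEFAULT_MEASURES, encoder: CovariateEncoder | None = None,
                 spline_df: int = 3) -> np.ndarray:
    """Measure-major stacked fixed effects on the encoded design.

    Declining pulmonary trends, mildly declining EF, rising RVSP;
    diffuse skin disease worse for lung, limited worse for RVSP.
    """
    encoder = encoder or CovariateEncoder()
    per_measure = {
        # intercept, age, race_black, race_other, gender_male, skin_diffuse,
        # aca, rnapol, scl70, ns1, ns2, ns3
        "pFVC": [0.4, -0.10, -0.20, -0.10, -0.10, -0.30, 0.10, 0.05, -0.35, -0.6, -0.9, -1.1],
        "pDLCO": [0.3, -0.12, -0.15, -0.08, -0.08, -0.25, 0.08, 0.05, -0.25, -0.5, -0.8, -1.0],
        "EF": [0.1, -0.15, -0.10, -0.05, -0.12, -0.10, 0.00, -0.05, -0.05, -0.2, -0.3, -0.45],
        "RVSP": [-0.2, 0.20, 0.10, 0.05, 0.10, -0.15, 0.25, 0.10, 0.05, 0.45, 0.7, 0.9],
    }
    p = encoder.n_columns + spline_df
    out = []
    for m in measures:
        coefs = per_measure.get(m)
        if coefs is None or len(coefs) != p:
            coefs = np.zeros(p)
            coefs[0] = 0.2
        out.append(np.asarray(coefs, dtype=float))
    return np.concatenate(out)


# ----------------------------------------------------------------------
@dataclass
class SimulationSpec:
    """Generative configuration; defaults are the package's reference
    study conditions."""

    m: int = 300
    measures: tuple[str, ...] = DEFAULT_MEASURES
    seed: int = 0
    beta: np.ndarray | None = None
    D: np.ndarray | None = None
    Sigma_e: np.ndarray | None = None
    n_visits_range: tuple[int, int] = (5, 15)
    gap_mean_years: float = 1.0
    #: patients present at varying disease durations; the first visit is
    #: drawn uniformly over this range of years since onset
    entry_time_range: tuple[float, float] = (0.0, 20.0)
    time_window: tuple[float, float] = (0.0, 40.0)
    missing_prob: float = 0.2
    warps: dict[str, Warp] | None = None
    events: list[EventDefinition] = field(default_factory=default_events)
    fixed: FixedSpec = field(default_factory=FixedSpec)
    random: RandomSpec = field(default_factory=RandomSpec)

    @property
    def K(self) -> int:
        return len(self.measures)

    def resolve(self):
        enc = CovariateEncoder()
        beta = self.beta if self.beta is not None else default_beta(
            self.measures, enc, self.fixed.spline_df
        )
        D = self.D if self.D is not None else default_D(self.K)
        Se = self.Sigma_e if self.Sigma_e is not None else default_Sigma_e(self.K)
        for name, mat in (("D", D), ("Sigma_e", Se)):
            mat = np.asarray(mat, dtype=float)
            if not np.allclose(mat, mat.T) or np.linalg.eigvalsh(mat).min() <= 0:
                raise ValueError(f"{name} truth must be symmetric positive definite")
        warps = self.warps if self.warps is not None else default_warps(self.measures)
        events = [ev for ev in self.events if ev.measure in self.measures]
        return enc, np.asarray(beta, float), np.asarray(D, float), np.asarray(Se, float), warps, events


@dataclass
class CohortTruth:
    """Generative truth accompanying a simulated cohort."""

    beta: np.ndarray
    D: np.ndarray
    Sigma_e: np.ndarray
    b: np.ndarray  # (m, Kq) measure-major
    latent: pd.DataFrame  # per latent cell: patient_id, time, measure, z, value, observed
    events: list[EventDefinition]
    measures: tuple[str, ...]


def _simulate_covariates(m: int, rng: np.random.Generator) -> pd.DataFrame:
    age = np.clip(rng.normal(45.0, 13.0, size=m), 18.0, 80.0)
    race = rng.choice(["white", "black", "other"], size=m, p=[0.6, 0.25, 0.15])
    gender = rng.choice(["female", "male"], size=m, p=[0.8, 0.2])
    skin = rng.choice(["limited", "diffuse"], size=m, p=[0.6, 0.4])
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(m)],
            "age_onset": age,
            "race": race,
            "gender": gender,
            "skin_subtype": skin,
            "aca": rng.binomial(1, 0.3, size=m),
            "rnapol": rng.binomial(1, 0.2, size=m),
            "scl70": rng.binomial(1, 0.25, size=m),
        }
    )


def simulate_cohort(spec: SimulationSpec) -> tuple[LongitudinalDataset, CohortTruth]:
    """Draw a cohort from the generative model; byte-identical under a seed."""
    rng = np.random.default_rng(spec.seed)
    enc, beta, D, Se, warps, events = spec.resolve()
    K, q = spec.K, spec.random.q
    Kq = K * q
    p = enc.n_columns + spec.fixed.spline_df
    B = beta.reshape(K, p).T  # (p, K) columns per measure

    cov_df = _simulate_covariates(spec.m, rng)
    cov_design = enc.encode(cov_df)
    Ld = np.linalg.cholesky(D)
    Le = np.linalg.cholesky(Se)
    lo, hi = spec.time_window

    b_all = (Ld @ rng.standard_normal((Kq, spec.m))).T  # (m, Kq)
    obs_rows, latent_rows = [], []
    for i in range(spec.m):
        pid = cov_df["patient_id"].iloc[i]
        n_v = int(rng.integers(spec.n_visits_range[0], spec.n_visits_range[1] + 1))
        gaps = rng.exponential(spec.gap_mean_years, size=n_v)
        gaps[0] = rng.uniform(*spec.entry_time_range)
        t = np.cumsum(gaps)
        t = t[(t >= lo) & (t <= hi)]
        if len(t) == 0:
            t = np.array([rng.uniform(lo, min(hi, 5.0))])
        anchor = float(t[-1])
        U = np.column_stack(
            [np.tile(cov_design[i], (len(t), 1)), spec.fixed.spline(t)]
        )
        W = spec.random.basis(t, anchor)
        Bi = b_all[i].reshape(K, q).T  # (q, K)
        E = rng.standard_normal((len(t), K)) @ Le.T
        Zmat = U @ B + W @ Bi + E  # (V, K) latent z
        observed = rng.random((len(t), K)) >= spec.missing_prob
        # guarantee at least one observed measure per visit
        none_obs = ~observed.any(axis=1)
        if none_obs.any():
            observed[none_obs, rng.integers(0, K, size=none_obs.sum())] = True
        for v, tv in enumerate(t):
            for k, m_name in enumerate(spec.measures):
                val = float(warps[m_name].forward(Zmat[v, k]))
                latent_rows.append(
                    (pid, float(tv), m_name, float(Zmat[v, k]), val, bool(observed[v, k]))
                )
                if observed[v, k]:
                    obs_rows.append((pid, float(tv), m_name, val))

    obs_df = pd.DataFrame(obs_rows, columns=["patient_id", "time_years", "measure", "value"])
    latent_df = pd.DataFrame(
        latent_rows, columns=["patient_id", "time_years", "measure", "z", "value", "observed"]
    )
    cfg = AnalysisConfig(
        measures=spec.measures,
        events=events,
        time_window=spec.time_window,
        apply_min_obs_filter=False,
    )
    if len(obs_df) == 0:
        cov_df = cov_df.iloc[:0]
    ds = LongitudinalDataset.from_frames(obs_df, cov_df, cfg)
    truth = CohortTruth(
        beta=beta, D=D, Sigma_e=Se, b=b_all, latent=latent_df,
        events=events, measures=spec.measures,
    )
    return ds, truth


def truth_event_rates(truth: CohortTruth, events: list[EventDefinition] | None = None,
                      observed_only: bool = False) -> pd.DataFrame:
    """Per-event empirical crossing rates over the latent clinical values."""
    events = events if events is not None else truth.events
    rows = []
    lat = truth.latent
    if observed_only:
        lat = lat[lat["observed"]]
    for ev in events:
        sub = lat[lat["measure"] == ev.measure]
        ind = ev.indicator(sub["value"].to_numpy())
        rows.append(
            {
                "label": ev.label,
                "measure": ev.measure,
                "severity": ev.severity,
                "n": len(ind),
                "n_events": int(ind.sum()),
                "rate": float(ind.mean()) if len(ind) else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("label")
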
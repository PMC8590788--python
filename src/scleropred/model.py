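"""High-level estimator: quantile-normalize, assemble designs, fit, predict.

:class:`BayesianMVLMM` is the clinic-facing object: ``fit`` takes a
:class:`~scleropred.data_model.LongitudinalDataset`, quantile-normalizes
each biomarker, builds the block design matrices and runs the Gibbs
sampler; ``predict_patient`` returns closed-form conditional trajectories
and event probabilities for any patient — including one never seen in
training, for whom only baseline covariates (cold start) or a fresh
history are available.  No refitting happens at prediction time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .data_model import LongitudinalDataset
from .design import (
    FixedSpec,
    RandomSpec,
    build_design_bundle,
    patient_design_from_obs,
)
from .mvlmm import MCMCSettings, PriorSpec, gibbs_fit
from .predict import (
    ChronologyError,
    PredictionResult,
    conditional_moments,
    event_probabilities,
)
from .preprocess import (
    apply_transforms,
    fit_quantile_transforms,
    transform_thresholds,
)

__all__ = ["BayesianMVLMM"]


class BayesianMVLMM(BaseEstimator):
    """Bayesian multivariate linear mixed model with dynamic prediction.

    Parameters
    ----------
    transform : bool
        Quantile-normalize biomarkers before fitting (default).  Disable
        when the data are already on a jointly Gaussian scale.
    priors, settings : PriorSpec, MCMCSettings
        Sampler configuration; see :mod:`scleropred.mvlmm`.
    fixed, random : FixedSpec, RandomSpec
        Design specification; see :mod:`scleropred.design`.
    """

    def __init__(
        self,
        transform: bool = True,
        plotting_position: str = "hazen",
        priors: PriorSpec | None = None,
        settings: MCMCSettings | None = None,
        fixed: FixedSpec | None = None,
        random: RandomSpec | None = None,
        visit_tolerance: float = 1.0 / 365.25,
        store_random_effects: bool = True,
    ):
        self.transform = transform
        self.plotting_position = plotting_position
        self.priors = priors
        self.settings = settings
        self.fixed = fixed
        self.random = random
        self.visit_tolerance = visit_tolerance
        self.store_random_effects = store_random_effects

    # ------------------------------------------------------------------
    def fit(self, ds: LongitudinalDataset, y=None) -> "BayesianMVLMM":
        fixed = self.fixed or FixedSpec()
        random = self.random or RandomSpec()
        self.measures_ = tuple(ds.measures)
        self.events_ = list(ds.events)
        self.measure_index_ = {m: k for k, m in enumerate(ds.measures)}
        if self.transform:
            self.transforms_ = fit_quantile_transforms(ds, self.plotting_position)
            zds = apply_transforms(ds, self.transforms_)
            self.z_thresholds_ = transform_thresholds(self.transforms_, ds.events)
        else:
            self.transforms_ = None
            zds = ds
            self.z_thresholds_ = {ev.label: float(ev.threshold) for ev in ds.events}
        self.bundle_ = build_design_bundle(zds, fixed, random, self.visit_tolerance)
        self.fixed_ = fixed
        self.random_ = random
        self.posterior_ = gibbs_fit(
            self.bundle_,
            priors=self.priors,
            settings=self.settings,
            store_random_effects=self.store_random_effects,
        )
        self.dataset_ = ds
        return self

    # ------------------------------------------------------------------
    def _to_z(self, measures_observed, values) -> np.ndarray:
        vals = np.asarray(values, dtype=float)
        if self.transforms_ is None:
            return vals
        out = np.empty_like(vals)
        meas = np.asarray(measures_observed)
        for m, qt in self.transforms_.items():
            sel = meas == m
            if sel.any():
                out[sel] = qt.transform(vals[sel])
        return out

    def predict_instance(
        self,
        cov_row: pd.DataFrame,
        hist_times,
        hist_measures,
        hist_values,
        target_time: float,
        params: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
        average_draws: bool = False,
        n_draws: int = 50,
        patient_id=None,
    ) -> PredictionResult:
        """One conditional prediction from an explicit history.

        ``hist_values`` are clinical-scale (transformed internally) and
        must all precede ``target_time`` strictly.  ``params`` defaults
        to posterior means; with ``average_draws`` the event
        probabilities (not the parameters) are averaged over posterior
        draws.
        """
        check_is_fitted(self, "posterior_")
        hist_times = np.asarray(hist_times, dtype=float)
        if len(hist_times) and hist_times.max() >= target_time:
            raise ChronologyError(
                f"target time {target_time} not after last history time "
                f"{hist_times.max()}"
            )
        zvals = self._to_z(hist_measures, hist_values)
        cov_design = self.bundle_.encoder.encode(cov_row)[0]
        pdg = patient_design_from_obs(
            hist_times, hist_measures, zvals, self.measures_,
            self.fixed_, self.random_, cov_design, self.visit_tolerance,
            patient_id=patient_id,
        )
        y, X, Z, vid, mid = pdg.stacked()
        Xp, Zp = pdg.target_design(target_time, self.fixed_, self.random_, cov_design)

        if average_draws:
            draws = self.posterior_.parameter_draws(n_draws)
        else:
            draws = [params or self.posterior_.point_params()]
        means, covs, probs = [], [], []
        for beta, D, Se in draws:
            mean, cov = conditional_moments(y, X, Z, vid, mid, Xp, Zp, beta, D, Se)
            means.append(mean)
            covs.append(cov)
            probs.append(
                event_probabilities(mean, cov, self.events_, self.z_thresholds_,
                                    self.measure_index_)
            )
        cond_mean = np.mean(means, axis=0)
        cond_cov = np.mean(covs, axis=0)
        event_probs = {
            lbl: float(np.mean([p[lbl] for p in probs])) for lbl in probs[0]
        }
        clinical = None
        if self.transforms_ is not None:
            clinical = np.array(
                [
                    self.transforms_[m].inverse_transform([cond_mean[k]])[0]
                    for m, k in self.measure_index_.items()
                ]
            )
        return PredictionResult(
            patient_id=patient_id,
            target_time=float(target_time),
            cond_mean=cond_mean,
            cond_cov=cond_cov,
            event_probs=event_probs,
            clinical_mean=clinical,
            n_history=len(hist_times),
        )

    # ------------------------------------------------------------------
    def predict_patient(
        self,
        ds: LongitudinalDataset,
        patient_id,
        target_times,
        average_draws: bool = False,
        n_draws: int = 50,
    ) -> list[PredictionResult]:
        """Predictions at future times for one patient of ``ds``.

        For each target time the history is every observation of that
        patient strictly before it; an empty history (cold start) still
        yields probabilities from covariates and population trends alone.
        """
        check_is_fitted(self, "posterior_")
        if patient_id not in set(ds.covariates.index):
            raise KeyError(f"unknown patient {patient_id!r}: covariates required")
        cov_row = ds.covariates.loc[[patient_id]]
        obs = ds.patient_observations(patient_id)
        results = []
        for tt in np.atleast_1d(np.asarray(target_times, dtype=float)):
            hist = obs[obs["time_years"] < tt]
            results.append(
                self.predict_instance(
                    cov_row,
                    hist["time_years"].to_numpy(),
                    hist["measure"].to_numpy(),
                    hist["value"].to_numpy(),
                    float(tt),
                    average_draws=average_draws,
                    n_draws=n_draws,
                    patient_id=patient_id,
                )
            )
        return results

    def predictions_frame(self, results: list[PredictionResult]) -> pd.DataFrame:
        """Flatten prediction results into an exportable table."""
        rows = []
        for r in results:
            row = {"patient_id": r.patient_id, "target_time": r.target_time,
                   "n_history": r.n_history}
            for m, k in self.measure_index_.items():
                row[f"mean_z_{m}"] = r.cond_mean[k]
                row[f"sd_z_{m}"] = float(np.sqrt(max(r.cond_cov[k, k], 0.0)))
                if r.clinical_mean is not None:
                    row[f"mean_{m}"] = r.clinical_mean[k]
            row.update({f"p_{lbl}": p for lbl, p in r.event_probs.items()})
            rows.append(row)
        return pd.DataFrame(rows)
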
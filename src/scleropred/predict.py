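"""Closed-form dynamic prediction of future biomarkers and event risks.

Given fitted parameters (beta, D, Sigma_e), the joint distribution of a
patient's observed history Y_i and the K-vector Y_+ at a future time is
Gaussian, so the predictive distribution is exact Gaussian conditioning:

    E(Y_+ | Y_i = y_i)  = X_+ beta + C' V_i^{-1} (y_i - X_i beta)
    Var(Y_+ | Y_i = y_i) = V_+ - C' V_i^{-1} C

with V_i = Z_i D Z_i' + Sigma_i, V_+ = Z_+ D Z_+' + Sigma_e, and
C = Z_i D Z_+'.  Event probabilities are one-dimensional Gaussian tail
areas of the conditional marginals evaluated at the z-scale thresholds;
because the quantile transform is monotone these equal the clinical
threshold-crossing probabilities exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_solve
from scipy.special import ndtr

from .data_model import EventDefinition
from .mvlmm import _jittered_cholesky

__all__ = [
    "ChronologyError",
    "PredictionResult",
    "residual_covariance",
    "conditional_moments",
    "event_probabilities",
]


class ChronologyError(ValueError):
    """Target time does not lie strictly after the conditioning history."""


@dataclass
class PredictionResult:
    """Conditional moments at one future time plus derived event risks."""

    patient_id: object
    target_time: float
    cond_mean: np.ndarray  # (K,) z scale
    cond_cov: np.ndarray  # (K, K) z scale
    event_probs: dict[str, float]
    clinical_mean: np.ndarray | None = None  # (K,) via inverse transform
    n_history: int = 0


def residual_covariance(
    visit_ids: np.ndarray, measure_ids: np.ndarray, Sigma_e: np.ndarray
) -> np.ndarray:
    """Sigma_i for stacked rows: Sigma_e entry when two rows share a visit,
    zero across visits."""
    same_visit = visit_ids[:, None] == visit_ids[None, :]
    return np.where(same_visit, Sigma_e[np.ix_(measure_ids, measure_ids)], 0.0)


def conditional_moments(
    y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    visit_ids: np.ndarray,
    measure_ids: np.ndarray,
    Xp: np.ndarray,
    Zp: np.ndarray,
    beta: np.ndarray,
    D: np.ndarray,
    Sigma_e: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact Gaussian conditioning of the future K-vector on the history.

    Empty history returns the marginal moments
    (X_+ beta, Z_+ D Z_+' + Sigma_e).
    """
    Vp = Zp @ D @ Zp.T + Sigma_e
    mu_p = Xp @ beta
    if len(y) == 0:
        return mu_p, Vp
    Vi = Z @ D @ Z.T + residual_covariance(visit_ids, measure_ids, Sigma_e)
    C = Z @ D @ Zp.T  # (n_i, K)
    L, _ = _jittered_cholesky(Vi)
    resid = y - X @ beta
    sol_r = cho_solve((L, True), resid)
    sol_C = cho_solve((L, True), C)
    mean = mu_p + C.T @ sol_r
    cov = Vp - C.T @ sol_C
    cov = 0.5 * (cov + cov.T)
    return mean, cov


def event_probabilities(
    cond_mean: np.ndarray,
    cond_cov: np.ndarray,
    events: list[EventDefinition],
    z_thresholds: dict[str, float],
    measure_index: dict[str, int],
) -> dict[str, float]:
    """Marginal per-event crossing probabilities from conditional moments.

    "below" events: Phi((c - mu_k)/sigma_k); "above": the complement.
    A degenerate sigma_k = 0 collapses to a 0/1 indicator.
    """
    out = {}
    sd = np.sqrt(np.clip(np.diag(cond_cov), 0.0, None))
    for ev in events:
        k = measure_index[ev.measure]
        c = z_thresholds[ev.label]
        if sd[k] == 0.0:
            below = 1.0 if cond_mean[k] < c else (0.5 if cond_mean[k] == c else 0.0)
        else:
            below = float(ndtr((c - cond_mean[k]) / sd[k]))
        out[ev.label] = below if ev.direction == "below" else 1.0 - below
    return out
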
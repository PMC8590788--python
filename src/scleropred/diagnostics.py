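"""Model-adequacy checks: residual Gaussianity, calibration, correlation.

The prediction machinery rests on joint Gaussianity of the transformed
biomarkers.  Marginal quantile normalization guarantees only the
marginals, so we examine model residuals: standardized marginally
(dividing by the marginal SDs from diag(V_i)) for per-measure Q-Q
plots, or whitened by the inverse Cholesky factor of V_i, which
decorrelates them and makes the joint test exact under the model.

Calibration compares observed with expected event counts within
quintiles of predicted probability via a Hosmer–Lemeshow-form
chi-square; the empirical correlation matrix summarizes cross-measure,
cross-year dependence of year-binned observations.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.special import ndtri
from scipy.stats import kstest

from .data_model import LongitudinalDataset
from .mvlmm import _jittered_cholesky
from .predict import residual_covariance

__all__ = [
    "standardized_residuals",
    "gaussianity_check",
    "calibration_chisq",
    "empirical_correlation_matrix",
]


def standardized_residuals(model, mode: str = "whitened") -> pd.DataFrame:
    """Jointly standardized residuals of a fitted :class:`BayesianMVLMM`.

    ``marginal`` divides each residual by its marginal SD from
    diag(V_i); ``whitened`` multiplies by the inverse Cholesky factor of
    V_i (fully decorrelated).  Returns one row per observation with the
    measure name attached.
    """
    if mode not in ("marginal", "whitened"):
        raise ValueError("mode must be 'marginal' or 'whitened'")
    beta, D, Se = model.posterior_.point_params()
    rows = []
    for pdg in model.bundle_.patients:
        y, X, Z, vid, mid = pdg.stacked()
        if len(y) == 0:
            continue
        Vi = Z @ D @ Z.T + residual_covariance(vid, mid, Se)
        r = y - X @ beta
        if mode == "marginal":
            u = r / np.sqrt(np.diag(Vi))
        else:
            L, _ = _jittered_cholesky(Vi)
            u = solve_triangular(L, r, lower=True)
        for j in range(len(y)):
            rows.append(
                {
                    "patient_id": pdg.patient_id,
                    "time_years": pdg.times[vid[j]],
                    "measure": model.measures_[mid[j]],
                    "residual": float(u[j]),
                }
            )
    return pd.DataFrame(rows)


def gaussianity_check(residuals, per_measure: bool = False) -> pd.DataFrame:
    """Q-Q coordinates against N(0,1) plus the Kolmogorov–Smirnov distance.

    ``residuals`` is either an array or the frame from
    :func:`standardized_residuals`; with ``per_measure`` the check is
    run separately per biomarker.  Gaussian quantiles use Hazen
    positions.  A single residual yields NaN KS (flagged).
    """
    if isinstance(residuals, pd.DataFrame):
        groups = (
            residuals.groupby("measure")["residual"] if per_measure
            else {"all": residuals["residual"]}.items()
        )
    else:
        groups = {"all": pd.Series(np.asarray(residuals, dtype=float))}.items()
    out = []
    for name, vals in groups:
        v = np.sort(np.asarray(vals, dtype=float))
        n = len(v)
        if n < 2:
            out.append(pd.DataFrame(
                {"measure": name, "sample_q": v, "gaussian_q": np.nan, "ks": np.nan}
            ))
            continue
        gq = ndtri((np.arange(1, n + 1) - 0.5) / n)
        ks = kstest(v, "norm").statistic
        out.append(pd.DataFrame(
            {"measure": name, "sample_q": v, "gaussian_q": gq, "ks": ks}
        ))
    return pd.concat(out, ignore_index=True)


def calibration_chisq(
    probabilities, outcomes, groups: int = 5
) -> tuple[float, pd.DataFrame]:
    """Hosmer–Lemeshow-form calibration statistic over probability quantile
    groups.

    Group boundaries are empirical quantiles of the predicted
    probabilities, ties assigned to the lower group.  Each term is
    (O_g - E_g)^2 / (E_g (1 - E_g/n_g)); a degenerate expected count is
    floored at 0.5 events (logged) so the statistic stays finite.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if groups < 2:
        raise ValueError("need at least 2 groups")
    edges = np.quantile(p, np.linspace(0, 1, groups + 1)[1:-1])
    gidx = np.searchsorted(edges, p, side="left")
    rows = []
    stat = 0.0
    floored = False
    for g in range(groups):
        sel = gidx == g
        n_g = int(sel.sum())
        if n_g == 0:
            rows.append({"group": g, "n": 0, "observed": 0, "expected": 0.0, "term": 0.0})
            continue
        O = float(y[sel].sum())
        E = float(p[sel].sum())
        E_eff = float(np.clip(E, 0.5, n_g - 0.5))
        floored |= E_eff != E
        denom = E_eff * (1.0 - E_eff / n_g)
        term = (O - E) ** 2 / denom
        stat += term
        rows.append({"group": g, "n": n_g, "observed": O, "expected": E, "term": term})
    if floored:
        warnings.warn("degenerate expected count floored in calibration statistic",
                      stacklevel=2)
    return float(stat), pd.DataFrame(rows)


def empirical_correlation_matrix(
    ds: LongitudinalDataset, years=range(0, 11), min_pairs: int = 3
) -> pd.DataFrame:
    """Pairwise-complete correlation of year-binned observations.

    Observations are binned to the nearest integer year (one value per
    patient-year-measure, mean when several); the result is a
    (K*n_years) square frame indexed by (measure, year), diagonal 1,
    cells with fewer than ``min_pairs`` complete pairs left NaN.
    """
    years = list(years)
    obs = ds.observations.copy()
    obs["year"] = np.rint(obs["time_years"]).astype(int)
    obs = obs[obs["year"].isin(years)]
    wide = obs.pivot_table(
        index="patient_id", columns=["measure", "year"], values="value", aggfunc="mean"
    )
    full_cols = pd.MultiIndex.from_product([list(ds.measures), years],
                                           names=["measure", "year"])
    wide = wide.reindex(columns=full_cols)
    corr = wide.corr(min_periods=min_pairs)
    np.fill_diagonal(corr.values, 1.0)
    return corr
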
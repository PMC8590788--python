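"""Quantile normalization of biomarkers to the standard-Gaussian scale.

Each biomarker is mapped through its empirical distribution function
composed with the inverse standard-normal CDF, z = Phi^{-1}(G_hat(y)).
Because the map is monotone, the probability of crossing a clinical
threshold is exactly preserved when the threshold is pushed through the
same map, which is what makes closed-form Gaussian event probabilities on
the z scale valid on the clinical scale.

The empirical CDF uses Hazen plotting positions (r - 0.5)/n with average
ranks for ties, linear interpolation on the probability scale between
order statistics, and probabilities clamped to [eps, 1 - eps] (default
eps = 1/(2n)) outside the observed range so every real value is mappable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy.special import ndtr, ndtri
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .data_model import EventDefinition, LongitudinalDataset

__all__ = [
    "DegenerateDistributionError",
    "GaussianQuantileTransformer",
    "fit_quantile_transform",
    "fit_quantile_transforms",
    "apply_transforms",
    "transform_thresholds",
]


class DegenerateDistributionError(ValueError):
    """All training values identical: no empirical distribution to invert."""


class GaussianQuantileTransformer(TransformerMixin, BaseEstimator):
    """Monotone map of one biomarker to the standard-Gaussian scale.

    Parameters
    ----------
    plotting_position : {"hazen", "weibull"}
        Rule assigning probabilities to order statistics: Hazen
        ``(r - 0.5)/n`` (default; keeps extremes finite) or Weibull
        ``r/(n + 1)``.
    clamp_eps : float or None
        Probability bound used for values outside the training range.
        ``None`` (default) uses ``1/(2n)``.
    """

    def __init__(self, plotting_position: str = "hazen", clamp_eps: float | None = None):
        self.plotting_position = plotting_position
        self.clamp_eps = clamp_eps

    # ------------------------------------------------------------------
    def fit(self, X, y=None) -> "GaussianQuantileTransformer":
        v = np.asarray(X, dtype=float).ravel()
        v = v[~np.isnan(v)]
        if v.size < 2 or np.unique(v).size < 2:
            raise DegenerateDistributionError(
                "need at least 2 distinct values to fit a quantile transform"
            )
        n = v.size
        ranks = rankdata(v, method="average")
        if self.plotting_position == "hazen":
            p = (ranks - 0.5) / n
        elif self.plotting_position == "weibull":
            p = ranks / (n + 1.0)
        else:
            raise ValueError(f"unknown plotting position {self.plotting_position!r}")
        order = np.argsort(v, kind="mergesort")
        vs, ps = v[order], p[order]
        # ties share one probability (average rank), so keep unique values
        keep = np.empty(n, dtype=bool)
        keep[:-1] = np.diff(vs) > 0
        keep[-1] = True
        self.support_values_ = vs[keep]
        self.support_probs_ = ps[keep]
        self.n_ = n
        self.clamp_eps_ = self.clamp_eps if self.clamp_eps is not None else 1.0 / (2 * n)
        if not (0 < self.clamp_eps_ < 0.5):
            raise ValueError("clamp_eps must lie in (0, 0.5)")
        return self

    # ------------------------------------------------------------------
    def transform(self, X) -> np.ndarray:
        """Clinical-scale values -> z scale (monotone, clamped outside range)."""
        check_is_fitted(self, "support_values_")
        v = np.asarray(X, dtype=float)
        p = np.interp(v, self.support_values_, self.support_probs_)
        p = np.clip(p, self.clamp_eps_, 1.0 - self.clamp_eps_)
        return ndtri(p)

    def inverse_transform(self, Z) -> np.ndarray:
        """z scale -> clinical scale; no extrapolation beyond observed support."""
        check_is_fitted(self, "support_values_")
        p = ndtr(np.asarray(Z, dtype=float))
        return np.interp(p, self.support_probs_, self.support_values_)

    def transform_threshold(self, threshold: float) -> float:
        """Push an event threshold through the same monotone map as the data."""
        return float(self.transform(np.asarray([threshold]))[0])

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        check_is_fitted(self, "support_values_")
        return {
            "plotting_position": self.plotting_position,
            "clamp_eps": self.clamp_eps_,
            "n": self.n_,
            "support_values": self.support_values_.tolist(),
            "support_probs": self.support_probs_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GaussianQuantileTransformer":
        qt = cls(plotting_position=d["plotting_position"], clamp_eps=d["clamp_eps"])
        qt.support_values_ = np.asarray(d["support_values"], dtype=float)
        qt.support_probs_ = np.asarray(d["support_probs"], dtype=float)
        qt.n_ = int(d["n"])
        qt.clamp_eps_ = float(d["clamp_eps"])
        return qt


# ----------------------------------------------------------------------
def fit_quantile_transform(
    values, plotting_position: str = "hazen", clamp_eps: float | None = None
) -> GaussianQuantileTransformer:
    """Functional wrapper around :class:`GaussianQuantileTransformer`."""
    return GaussianQuantileTransformer(plotting_position, clamp_eps).fit(values)


def fit_quantile_transforms(
    ds: LongitudinalDataset, plotting_position: str = "hazen"
) -> dict[str, GaussianQuantileTransformer]:
    """Fit one transform per measure on the dataset's observed values."""
    out = {}
    for m in ds.measures:
        vals = ds.observations.loc[ds.observations["measure"] == m, "value"].to_numpy()
        out[m] = fit_quantile_transform(vals, plotting_position)
    return out


def apply_transforms(
    ds: LongitudinalDataset, transforms: dict[str, GaussianQuantileTransformer]
) -> LongitudinalDataset:
    """Return a dataset whose values are on the z scale."""
    z = np.empty(len(ds.observations))
    meas = ds.observations["measure"].to_numpy()
    vals = ds.observations["value"].to_numpy()
    for m, qt in transforms.items():
        sel = meas == m
        z[sel] = qt.transform(vals[sel])
    return ds.with_values(z)


def transform_thresholds(
    transforms: dict[str, GaussianQuantileTransformer],
    events: list[EventDefinition],
) -> dict[str, float]:
    """Map each event threshold to the z scale; directions are unchanged."""
    out = {}
    for ev in events:
        if ev.measure not in transforms:
            raise KeyError(f"no transform fitted for measure {ev.measure!r}")
        out[ev.label] = transforms[ev.measure].transform_threshold(ev.threshold)
    return out


def save_transforms(transforms: dict[str, GaussianQuantileTransformer], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({m: qt.to_dict() for m, qt in transforms.items()}, fh)


def load_transforms(path: str | Path) -> dict[str, GaussianQuantileTransformer]:
    with open(path) as fh:
        raw = json.load(fh)
    return {m: GaussianQuantileTransformer.from_dict(d) for m, d in raw.items()}
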
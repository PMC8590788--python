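"""Closed-form conditional prediction and event probabilities."""

import numpy as np
import pytest
from scipy.special import ndtr

from scleropred.data_model import EventDefinition
from scleropred.predict import (
    ChronologyError,
    conditional_moments,
    event_probabilities,
    residual_covariance,
)


def _empty_history(K, p, q):
    return (np.empty(0), np.empty((0, K * p)), np.empty((0, K * q)),
            np.empty(0, dtype=int), np.empty(0, dtype=int))


def test_empty_history_returns_marginal_moments(rng):
    K, p, q = 2, 3, 2
    beta = rng.normal(size=K * p)
    A = rng.normal(size=(K * q, K * q))
    D = A @ A.T + np.eye(K * q)
    Se = np.array([[0.3, 0.1], [0.1, 0.4]])
    Xp = rng.normal(size=(K, K * p))
    Zp = rng.normal(size=(K, K * q))
    mean, cov = conditional_moments(*_empty_history(K, p, q), Xp, Zp, beta, D, Se)
    assert np.allclose(mean, Xp @ beta)
    assert np.allclose(cov, Zp @ D @ Zp.T + Se)


def test_univariate_random_intercept_shrinkage_closed_form():
    """cond mean = x'beta + (n d / (n d + s2)) * rbar for K=1, intercept RE."""
    d, s2, n = 0.9, 0.3, 4
    beta = np.array([1.5])
    y = np.array([2.0, 2.5, 1.8, 2.2])
    X = np.ones((n, 1))
    Z = np.ones((n, 1))
    vid = np.arange(n)
    mid = np.zeros(n, dtype=int)
    Xp = np.ones((1, 1))
    Zp = np.ones((1, 1))
    mean, cov = conditional_moments(
        y, X, Z, vid, mid, Xp, Zp, beta, np.array([[d]]), np.array([[s2]])
    )
    rbar = (y - 1.5).mean()
    w = n * d / (n * d + s2)
    assert mean[0] == pytest.approx(1.5 + w * rbar, rel=1e-10)
    assert cov[0, 0] == pytest.approx(d + s2 - w * d, rel=1e-10)


def test_conditioning_matches_monte_carlo_regression(rng):
    """Random K=2 instance: moments agree with regression on 200k joint draws."""
    K, n = 2, 4
    p, q = 2, 2
    X = rng.normal(size=(n, K * p))
    Z = rng.normal(size=(n, K * q))
    vid = np.array([0, 0, 1, 2])
    mid = np.array([0, 1, 0, 1])
    Xp = rng.normal(size=(K, K * p))
    Zp = rng.normal(size=(K, K * q))
    beta = rng.normal(size=K * p)
    A = rng.normal(size=(K * q, K * q)) / 2
    D = A @ A.T + 0.5 * np.eye(K * q)
    B = rng.normal(size=(K, K)) / 3
    Se = B @ B.T + 0.3 * np.eye(K)

    Vi = Z @ D @ Z.T + residual_covariance(vid, mid, Se)
    C = Z @ D @ Zp.T
    Vp = Zp @ D @ Zp.T + Se
    joint_cov = np.block([[Vi, C], [C.T, Vp]])
    joint_mean = np.concatenate([X @ beta, Xp @ beta])
    L = np.linalg.cholesky(joint_cov)
    N = 200_000
    draws = joint_mean + rng.standard_normal((N, n + K)) @ L.T
    Yh, Yp = draws[:, :n], draws[:, n:]

    y_obs = joint_mean[:n] + np.linalg.cholesky(Vi) @ rng.standard_normal(n)
    mean, cov = conditional_moments(y_obs, X, Z, vid, mid, Xp, Zp, beta, D, Se)

    design = np.column_stack([np.ones(N), Yh])
    coef, *_ = np.linalg.lstsq(design, Yp, rcond=None)
    pred = np.array([1.0, *y_obs]) @ coef
    resid = Yp - design @ coef
    mc_cov = resid.T @ resid / (N - n - 1)
    gram_inv = np.linalg.inv(design.T @ design)
    lever = np.array([1.0, *y_obs]) @ gram_inv @ np.array([1.0, *y_obs])
    for k in range(K):
        se = np.sqrt(mc_cov[k, k] * lever)
        assert abs(mean[k] - pred[k]) < 3 * se
    for a in range(K):
        for b in range(K):
            se = np.sqrt((mc_cov[a, a] * mc_cov[b, b] + mc_cov[a, b] ** 2) / N)
            assert abs(cov[a, b] - mc_cov[a, b]) < 4 * se


@pytest.mark.parametrize("direction,expected", [("below", 0.5), ("above", 0.5)])
def test_probability_half_when_mean_at_threshold(direction, expected):
    ev = EventDefinition("pFVC", 70.0, direction, "mild", "x")
    probs = event_probabilities(
        np.array([0.0]), np.array([[1.0]]), [ev], {"x": 0.0}, {"pFVC": 0}
    )
    assert probs["x"] == pytest.approx(expected)


def test_probability_one_sd_above_threshold():
    ev = EventDefinition("RVSP", 45.0, "above", "mild", "r")
    probs = event_probabilities(
        np.array([1.0]), np.array([[1.0]]), [ev], {"r": 0.0}, {"RVSP": 0}
    )
    assert probs["r"] == pytest.approx(1 - ndtr(-1.0), rel=1e-9)


def test_degenerate_variance_gives_indicator():
    ev = EventDefinition("pFVC", 70.0, "below", "mild", "x")
    probs = event_probabilities(
        np.array([-1.0]), np.array([[0.0]]), [ev], {"x": 0.0}, {"pFVC": 0}
    )
    assert probs["x"] == 1.0


def test_probability_monotone_in_threshold():
    ev1 = EventDefinition("pFVC", 60.0, "below", "severe", "s")
    ev2 = EventDefinition("pFVC", 70.0, "below", "mild", "m")
    probs = event_probabilities(
        np.array([0.2]), np.array([[0.5]]), [ev1, ev2],
        {"s": -1.0, "m": -0.3}, {"pFVC": 0},
    )
    assert probs["s"] <= probs["m"]


def test_history_never_increases_variance(fitted_small_model, small_cohort):
    ds, _ = small_cohort
    pid = ds.patient_ids[2]
    obs = ds.patient_observations(pid)
    t_max = obs["time_years"].max()
    model = fitted_small_model
    cov_row = ds.covariates.loc[[pid]]
    full = model.predict_instance(
        cov_row, obs["time_years"], obs["measure"], obs["value"], t_max + 1.0
    )
    cold = model.predict_instance(cov_row, [], [], [], t_max + 1.0)
    assert np.all(np.diag(full.cond_cov) <= np.diag(cold.cond_cov) + 1e-9)


def test_cold_start_patient_gets_probabilities(fitted_small_model, small_cohort):
    ds, _ = small_cohort
    res = fitted_small_model.predict_instance(
        ds.covariates.iloc[[0]], [], [], [], 5.0
    )
    assert res.n_history == 0
    for p in res.event_probs.values():
        assert 0.0 <= p <= 1.0


def test_chronology_violation_rejected(fitted_small_model, small_cohort):
    ds, _ = small_cohort
    pid = ds.patient_ids[0]
    obs = ds.patient_observations(pid)
    with pytest.raises(ChronologyError):
        fitted_small_model.predict_instance(
            ds.covariates.loc[[pid]], obs["time_years"], obs["measure"],
            obs["value"], float(obs["time_years"].min()),
        )


def test_unknown_patient_without_covariates_rejected(fitted_small_model, small_cohort):
    ds, _ = small_cohort
    with pytest.raises(KeyError):
        fitted_small_model.predict_patient(ds, "no-such-patient", [5.0])


def test_draw_averaged_probability_within_per_draw_range(fitted_small_model, small_cohort):
    ds, _ = small_cohort
    pid = ds.patient_ids[1]
    obs = ds.patient_observations(pid)
    t_target = obs["time_years"].max() + 1.0
    model = fitted_small_model
    cov_row = ds.covariates.loc[[pid]]
    hist = (obs["time_years"], obs["measure"], obs["value"])
    avg = model.predict_instance(cov_row, *hist, t_target, average_draws=True, n_draws=20)
    per_draw = [
        model.predict_instance(cov_row, *hist, t_target, params=d)
        for d in model.posterior_.parameter_draws(20)
    ]
    for lbl, pavg in avg.event_probs.items():
        vals = [r.event_probs[lbl] for r in per_draw]
        assert min(vals) - 1e-12 <= pavg <= max(vals) + 1e-12
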
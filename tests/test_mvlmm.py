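"""Gibbs sampler correctness, convergence diagnostics, summaries."""

import warnings

import numpy as np
import pytest

from scleropred import MCMCSettings, RandomSpec, SimulationSpec, simulate_cohort
from scleropred.design import FixedSpec, build_design_bundle
from scleropred.mvlmm import gibbs_fit, posterior_summary, psrf, psrf_many
from scleropred.synthetic import Warp, default_Sigma_e


# ----------------------------------------------------------------------
# PSRF
# ----------------------------------------------------------------------
def test_psrf_identical_chains_hand_value():
    chains = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
    assert psrf(chains) == pytest.approx(np.sqrt(2.0 / 3.0))


def test_psrf_approaches_one_for_long_stationary_chains(rng):
    chains = rng.normal(size=(2, 20_000))
    assert abs(psrf(chains) - 1.0) < 0.01


def test_psrf_detects_disjoint_chains(rng):
    chains = np.stack([rng.normal(0, 1, 500), rng.normal(100, 1, 500)])
    assert psrf(chains) > 10.0


def test_psrf_single_chain_error():
    with pytest.raises(ValueError, match="split"):
        psrf(np.ones((1, 10)))


def test_psrf_many_matches_scalar(rng):
    draws = rng.normal(size=(3, 200, 4))
    vec = psrf_many(draws)
    for j in range(4):
        assert vec[j] == pytest.approx(psrf(draws[:, :, j]))


# ----------------------------------------------------------------------
# Sampler
# ----------------------------------------------------------------------
def test_retained_draw_count_and_pd_draws(fitted_small_model):
    post = fitted_small_model.posterior_
    s = post.settings
    assert post.beta.shape[:2] == (2, s.n_retained)
    for Dd in post.D.reshape(-1, *post.D.shape[-2:])[::37]:
        np.linalg.cholesky(Dd)  # symmetric positive definite
        assert np.allclose(Dd, Dd.T)
    for Sd in post.Sigma_e.reshape(-1, *post.Sigma_e.shape[-2:])[::37]:
        np.linalg.cholesky(Sd)


def test_same_seed_reproducible(small_cohort):
    ds, _ = small_cohort
    bundle = build_design_bundle(ds)
    kw = dict(settings=MCMCSettings(n_iter=120, burn_in=40, thin=2, n_chains=1, seed=9))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p1 = gibbs_fit(bundle, **kw)
        p2 = gibbs_fit(bundle, **kw)
    assert np.array_equal(p1.beta, p2.beta)
    assert np.array_equal(p1.D, p2.D)


def test_univariate_random_intercept_matches_reml():
    """K=1 random-intercept posterior means agree with an independent
    restricted-likelihood fit within 3 posterior SDs."""
    import pandas as pd
    import statsmodels.api as sm

    rs = RandomSpec(slope=False, hinge_offsets=())
    spec = SimulationSpec(
        m=80, measures=("pFVC",), seed=31, D=np.array([[1.0]]),
        Sigma_e=np.array([[0.25]]), random=rs, warps={"pFVC": Warp()},
    )
    ds, truth = simulate_cohort(spec)
    bundle = build_design_bundle(ds, FixedSpec(), rs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        post = gibbs_fit(
            bundle,
            settings=MCMCSettings(n_iter=3000, burn_in=600, thin=2, n_chains=1, seed=3),
        )
    rows = []
    for pdg in bundle.patients:
        y, X, Z, vid, mid = pdg.stacked()
        for i in range(len(y)):
            rows.append({"y": y[i], "g": str(pdg.patient_id),
                         **{f"x{j}": X[i, j] for j in range(X.shape[1])}})
    df = pd.DataFrame(rows)
    exog = df[[f"x{j}" for j in range(bundle.p)]].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.MixedLM(df["y"], exog, groups=df["g"]).fit(reml=True)
    beta_sd = post.beta.reshape(-1, bundle.p).std(axis=0)
    assert np.all(np.abs(post.beta_mean - fit.fe_params.to_numpy()) < 3 * beta_sd)
    d_draws = post.D.reshape(-1)
    assert abs(post.D_mean[0, 0] - fit.cov_re.iloc[0, 0]) < 3 * d_draws.std()
    s_draws = post.Sigma_e.reshape(-1)
    assert abs(post.Sigma_e_mean[0, 0] - fit.scale) < 3 * s_draws.std()


def test_marginal_covariance_identity_on_simulation(rng):
    """Empirical covariance of stacked simulated responses matches
    Z D Z' + Sigma (the marginal covariance the model implies)."""
    from scleropred.predict import residual_covariance

    rs = RandomSpec(slope=False, hinge_offsets=())
    D = np.array([[0.8, 0.3], [0.3, 0.6]])
    Se = default_Sigma_e(2, sd=0.5)
    spec = SimulationSpec(
        m=1, measures=("pFVC", "pDLCO"), seed=5, D=D, Sigma_e=Se, random=rs,
        n_visits_range=(6, 6), missing_prob=0.0,
        warps={"pFVC": Warp(), "pDLCO": Warp()},
    )
    ds, _ = simulate_cohort(spec)
    bundle = build_design_bundle(ds, FixedSpec(), rs)
    pdg = bundle.patients[0]
    y, X, Z, vid, mid = pdg.stacked()
    V_model = Z @ D @ Z.T + residual_covariance(vid, mid, Se)
    # re-simulate the same patient's responses many times
    n_rep = 4000
    L_D = np.linalg.cholesky(D)
    L_e = np.linalg.cholesky(Se)
    V = len(pdg.times)
    sims = np.empty((n_rep, len(y)))
    for r in range(n_rep):
        b = L_D @ rng.standard_normal(2)
        E = rng.standard_normal((V, 2)) @ L_e.T
        Ymat = np.outer(np.ones(V), b) + E
        sims[r] = np.array([Ymat[vid[i], mid[i]] for i in range(len(y))])
    emp = np.cov(sims.T)
    assert np.abs(emp - V_model).max() < 0.12


def test_posterior_summary_quantiles_match_naive_recount(fitted_small_model):
    post = fitted_small_model.posterior_
    summ = posterior_summary(post, include=("beta",))
    name = summ.index[0]
    pooled = np.sort(post.beta[:, :, 0].ravel())
    assert summ.loc[name, "q2.5"] == pytest.approx(np.quantile(pooled, 0.025))
    assert summ.loc[name, "q97.5"] == pytest.approx(np.quantile(pooled, 0.975))
    assert summ.loc[name, "mean"] == pytest.approx(pooled.mean())


def test_summary_invariant_to_chain_order(fitted_small_model):
    post = fitted_small_model.posterior_
    from dataclasses import replace

    flipped = replace(
        post,
        beta=post.beta[::-1].copy(),
        D=post.D[::-1].copy(),
        Sigma_e=post.Sigma_e[::-1].copy(),
        b=None,
    )
    a = posterior_summary(post, include=("beta",))
    b = posterior_summary(flipped, include=("beta",))
    assert np.allclose(a["mean"].to_numpy(), b["mean"].to_numpy())
    assert np.allclose(a["psrf"].to_numpy(), b["psrf"].to_numpy())


def test_settings_validation():
    with pytest.raises(ValueError):
        MCMCSettings(n_iter=100, burn_in=100)
    with pytest.raises(ValueError):
        MCMCSettings(n_iter=100, burn_in=10, thin=0)
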
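"""Bayesian multivariate linear mixed model estimated by Gibbs sampling.

Model (z scale, per patient i):

    Y_i = X_i beta + Z_i b_i + e_i,
    b_i ~ N_{Kq}(0, D),   e_i ~ N(0, Sigma_i),

where X_i, Z_i are block diagonal by measure.  The residual covariance
Sigma_i is block diagonal by *visit*: the K measures recorded at one
visit share an unstructured K x K covariance Sigma_e, while residuals at
distinct visits are independent.  This trait-by-unit structure keeps the
inverse-Wishart update conjugate and matches how multi-response mixed
models are conventionally parameterized.

Priors are diffuse conjugate: independent N(0, v_beta) on each fixed
effect (default v_beta = 1e8), inverse-Wishart on D (df = Kq + 1, scale
0.01 I) and on Sigma_e (df = K + 1, scale 0.01 I) — as diffuse as the
conjugate class allows while staying proper.  Measures missing at an
observed visit are imputed each sweep from their conditional Gaussian
given the observed components (data augmentation), which is how the
model absorbs arbitrary missingness patterns without deleting visits.

Because all full conditionals are Gaussian or inverse-Wishart the
sampler is a plain Gibbs cycle; each update is vectorized across
patients/visits so cohort-scale chains run in seconds per thousand
iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.stats import invwishart
from sklearn.base import BaseEstimator

from .design import DesignBundle

__all__ = [
    "PriorSpec",
    "MCMCSettings",
    "MVLMMPosterior",
    "gibbs_fit",
    "psrf",
    "psrf_many",
    "posterior_summary",
]


class FitError(RuntimeError):
    """The sampler could not proceed (persistent numerical failure)."""


@dataclass
class PriorSpec:
    """Diffuse conjugate priors.

    ``nu_D``/``nu_Sigma`` default to dimension + 1 (the smallest proper
    choice); scale matrices are ``s * I``.
    """

    v_beta: float = 1e8
    nu_D: int | None = None
    s_D: float = 0.01
    nu_Sigma: int | None = None
    s_Sigma: float = 0.01

    def resolve(self, dim_D: int, K: int) -> tuple[int, np.ndarray, int, np.ndarray]:
        nu_D = self.nu_D if self.nu_D is not None else dim_D + 1
        nu_S = self.nu_Sigma if self.nu_Sigma is not None else K + 1
        if nu_D < dim_D or nu_S < K:
            raise ValueError("inverse-Wishart degrees of freedom below dimension")
        return nu_D, self.s_D * np.eye(dim_D), nu_S, self.s_Sigma * np.eye(K)


@dataclass
class MCMCSettings:
    """Chain length and bookkeeping.  Reference run: 50,000 iterations,
    burn-in 2,000, thinning 10; scale down for simulation studies."""

    n_iter: int = 50_000
    burn_in: int = 2_000
    thin: int = 10
    n_chains: int = 2
    seed: int = 0
    chain_seeds: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_iter <= self.burn_in:
            raise ValueError("n_iter must exceed burn_in")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in + self.thin - 1) // self.thin

    def seeds(self) -> list[int]:
        if self.chain_seeds is not None:
            if len(self.chain_seeds) != self.n_chains:
                raise ValueError("chain_seeds length must equal n_chains")
            return list(self.chain_seeds)
        return [self.seed + 1000 * c for c in range(self.n_chains)]


# ----------------------------------------------------------------------
def _jittered_cholesky(a: np.ndarray, max_tries: int = 3):
    """Lower Cholesky with trace-scaled jitter on failure; counts retries."""
    jitter = 0.0
    for attempt in range(max_tries + 1):
        try:
            return cholesky(a + jitter * np.eye(a.shape[0]), lower=True), attempt
        except np.linalg.LinAlgError:
            base = 1e-10 * np.trace(a) / a.shape[0]
            jitter = base * 10.0**attempt if base > 0 else 10.0 ** (attempt - 12)
    raise FitError("persistent non-positive-definite conditional covariance")


@dataclass
class _SamplerData:
    """Flattened cohort arrays shared by every chain."""

    U: np.ndarray  # (N, p) per-visit fixed rows
    W: np.ndarray  # (N, q)
    Yobs: np.ndarray  # (N, K) NaN where missing
    mask: np.ndarray  # (N, K)
    pat: np.ndarray  # (N,) patient index, sorted
    starts: np.ndarray  # (m,) first row of each patient
    G: np.ndarray  # (m, q, q) = W_i' W_i
    UtU: np.ndarray  # (p, p)
    patterns: list  # (obs_idx, mis_idx, row_idx) per missingness pattern
    m: int
    K: int
    p: int
    q: int


def _prepare(bundle: DesignBundle) -> _SamplerData:
    Us, Ws, Ys, pats = [], [], [], []
    for i, pdg in enumerate(bundle.patients):
        Us.append(pdg.U)
        Ws.append(pdg.W)
        Ys.append(pdg.Y)
        pats.append(np.full(pdg.n_visits, i))
    U = np.vstack(Us)
    W = np.vstack(Ws)
    Y = np.vstack(Ys)
    pat = np.concatenate(pats)
    mask = ~np.isnan(Y)
    if not mask.any(axis=1).all():
        raise ValueError("visit with no observed measure")
    m = bundle.n_patients
    starts = np.searchsorted(pat, np.arange(m))
    G = np.stack([w.T @ w for w in Ws])
    keys, inverse = np.unique(mask, axis=0, return_inverse=True)
    patterns = []
    for g, key in enumerate(keys):
        if key.all():
            continue
        rows = np.where(inverse == g)[0]
        patterns.append((np.where(key)[0], np.where(~key)[0], rows))
    return _SamplerData(
        U=U, W=W, Yobs=Y, mask=mask, pat=pat, starts=starts, G=G, UtU=U.T @ U,
        patterns=patterns, m=m, K=bundle.K, p=bundle.p, q=bundle.q,
    )


def _segment_sum(arr: np.ndarray, starts: np.ndarray) -> np.ndarray:
    """Sum rows of ``arr`` within contiguous patient segments."""
    return np.add.reduceat(arr, starts, axis=0)


def _run_chain(
    data: _SamplerData,
    nu_D: int,
    S_D: np.ndarray,
    nu_S: np.ndarray,
    S_S: np.ndarray,
    v_beta: float,
    settings: MCMCSettings,
    rng: np.random.Generator,
    fix_D: np.ndarray | None,
    fix_Sigma: np.ndarray | None,
    store_b: bool,
):
    m, K, p, q = data.m, data.K, data.p, data.q
    Kq, pK = K * q, p * K
    N = data.U.shape[0]

    # --- initialization -------------------------------------------------
    Yc = data.Yobs.copy()
    col_mean = np.nanmean(np.where(data.mask, Yc, np.nan), axis=0)
    col_mean = np.nan_to_num(col_mean)
    for k in range(K):
        Yc[~data.mask[:, k], k] = col_mean[k]
    ridge = data.UtU + 1e-6 * np.trace(data.UtU) / p * np.eye(p)
    B = np.linalg.solve(ridge, data.U.T @ Yc)  # (p, K)
    B += 0.1 * rng.standard_normal(B.shape)  # mildly dispersed starts
    Bi = np.zeros((m, q, K))
    E0 = Yc - data.U @ B
    Se = fix_Sigma.copy() if fix_Sigma is not None else np.atleast_2d(np.cov(E0.T)) + 0.1 * np.eye(K)
    D = fix_D.copy() if fix_D is not None else np.eye(Kq)

    n_ret = settings.n_retained
    beta_draws = np.empty((n_ret, pK))
    D_draws = np.empty((n_ret, Kq, Kq))
    Se_draws = np.empty((n_ret, K, K))
    b_draws = np.empty((n_ret, m, Kq)) if store_b else None
    n_jitter = 0
    eye_pK = np.eye(pK)

    for it in range(settings.n_iter):
        # (5') data augmentation: impute missing cells given current params
        rand = np.einsum("nq,nqk->nk", data.W, Bi[data.pat])
        mu = data.U @ B + rand
        for obs_idx, mis_idx, rows in data.patterns:
            Soo = Se[np.ix_(obs_idx, obs_idx)]
            Smo = Se[np.ix_(mis_idx, obs_idx)]
            Smm = Se[np.ix_(mis_idx, mis_idx)]
            c, nj = _jittered_cholesky(Soo)
            n_jitter += nj
            Amap = cho_solve((c, True), Smo.T).T  # (|M|, |O|)
            cc = Smm - Amap @ Smo.T
            Lc, nj = _jittered_cholesky(cc)
            n_jitter += nj
            resid_o = Yc[np.ix_(rows, obs_idx)] - mu[np.ix_(rows, obs_idx)]
            noise = rng.standard_normal((len(rows), len(mis_idx))) @ Lc.T
            Yc[np.ix_(rows, mis_idx)] = (
                mu[np.ix_(rows, mis_idx)] + resid_o @ Amap.T + noise
            )

        cse, nj = _jittered_cholesky(Se)
        n_jitter += nj
        Seinv = cho_solve((cse, True), np.eye(K))
        cd, nj = _jittered_cholesky(D)
        n_jitter += nj
        Dinv = cho_solve((cd, True), np.eye(Kq))

        # (1) random effects b_i | ...
        R = Yc - data.U @ B  # (N, K)
        T = _segment_sum(data.W[:, :, None] * R[:, None, :], data.starts)  # (m,q,K)
        prec = np.einsum("ab,icd->iacbd", Seinv, data.G).reshape(m, Kq, Kq) + Dinv
        rhs = np.einsum("iqk,kl->ilq", T, Seinv).reshape(m, Kq)  # order (k, c)
        L = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, rhs[..., None])[..., 0]
        z = rng.standard_normal((m, Kq, 1))
        bvec = mean + np.linalg.solve(np.swapaxes(L, 1, 2), z)[..., 0]
        Bi = bvec.reshape(m, K, q).transpose(0, 2, 1)  # (m, q, K)

        # (2) fixed effects beta | ...
        rand = np.einsum("nq,nqk->nk", data.W, Bi[data.pat])
        R2 = Yc - rand
        A = np.kron(Seinv, data.UtU) + eye_pK / v_beta
        rhs_b = (data.U.T @ R2 @ Seinv).T.ravel()
        La, nj = _jittered_cholesky(A)
        n_jitter += nj
        mean_b = cho_solve((La, True), rhs_b)
        zb = rng.standard_normal(pK)
        bdraw = mean_b + solve_triangular(La.T, zb, lower=False)
        B = bdraw.reshape(K, p).T

        # (3) D | b
        if fix_D is None:
            Vmat = Bi.transpose(0, 2, 1).reshape(m, Kq)
            D = invwishart.rvs(df=nu_D + m, scale=S_D + Vmat.T @ Vmat, random_state=rng)
            D = np.atleast_2d(D)

        # (4) Sigma_e | residuals
        if fix_Sigma is None:
            E = R2 - data.U @ B
            Se = invwishart.rvs(df=int(nu_S + N), scale=S_S + E.T @ E, random_state=rng)
            Se = np.atleast_2d(Se)

        if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
            j = (it - settings.burn_in) // settings.thin
            beta_draws[j] = bdraw
            D_draws[j] = D
            Se_draws[j] = Se
            if store_b:
                b_draws[j] = Bi.transpose(0, 2, 1).reshape(m, Kq)

    return beta_draws, D_draws, Se_draws, b_draws, n_jitter


# ----------------------------------------------------------------------
@dataclass
class MVLMMPosterior:
    """Retained Gibbs draws, per chain, plus metadata.

    Shapes: ``beta`` (C, T, Kp), ``D`` (C, T, Kq, Kq), ``Sigma_e``
    (C, T, K, K), ``b`` (C, T, m, Kq) or None.  Fixed-effect ordering is
    measure-major: (beta_1', ..., beta_K')'.
    """

    beta: np.ndarray
    D: np.ndarray
    Sigma_e: np.ndarray
    b: np.ndarray | None
    measures: tuple[str, ...]
    fixed_names: list[str]
    patient_ids: list
    settings: MCMCSettings
    n_jitter: int = 0

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    @property
    def beta_mean(self) -> np.ndarray:
        return self.beta.reshape(-1, self.beta.shape[-1]).mean(axis=0)

    @property
    def D_mean(self) -> np.ndarray:
        return self.D.reshape(-1, *self.D.shape[-2:]).mean(axis=0)

    @property
    def Sigma_e_mean(self) -> np.ndarray:
        return self.Sigma_e.reshape(-1, *self.Sigma_e.shape[-2:]).mean(axis=0)

    def point_params(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(beta, D, Sigma_e) posterior means — plug-in prediction params."""
        return self.beta_mean, self.D_mean, self.Sigma_e_mean

    def parameter_draws(self, n_draws: int, seed: int = 0):
        """Subsample pooled (beta, D, Sigma_e) draws for draw-averaged prediction."""
        beta = self.beta.reshape(-1, self.beta.shape[-1])
        D = self.D.reshape(-1, *self.D.shape[-2:])
        Se = self.Sigma_e.reshape(-1, *self.Sigma_e.shape[-2:])
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(beta), size=min(n_draws, len(beta)), replace=False)
        return [(beta[i], D[i], Se[i]) for i in idx]

    # ------------------------------------------------------------------
    def monitored_chains(self, include=("beta", "b", "D")) -> dict[str, np.ndarray]:
        """Named scalar chains (C, T) for convergence monitoring."""
        out = {}
        if "beta" in include:
            for j, name in enumerate(self.fixed_names):
                out[f"beta[{name}]"] = self.beta[:, :, j]
        if "D" in include:
            Kq = self.D.shape[-1]
            for a in range(Kq):
                for bb in range(a, Kq):
                    out[f"D[{a},{bb}]"] = self.D[:, :, a, bb]
        if "Sigma_e" in include:
            K = self.Sigma_e.shape[-1]
            for a in range(K):
                for bb in range(a, K):
                    out[f"Sigma_e[{a},{bb}]"] = self.Sigma_e[:, :, a, bb]
        if "b" in include and self.b is not None:
            m, Kq = self.b.shape[2], self.b.shape[3]
            for i in range(m):
                for j in range(Kq):
                    out[f"b[{self.patient_ids[i]},{j}]"] = self.b[:, :, i, j]
        return out

    def max_psrf(self, include=("beta", "b", "D")) -> tuple[float, pd.Series]:
        """Maximum Gelman–Rubin PSRF over the monitored scalars."""
        chains = self.monitored_chains(include)
        vals = pd.Series({name: psrf(c) for name, c in chains.items()})
        return float(vals.max()), vals

    def save_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("beta", data=self.beta)
            f.create_dataset("D", data=self.D)
            f.create_dataset("Sigma_e", data=self.Sigma_e)
            if self.b is not None:
                f.create_dataset("b", data=self.b)
            f.attrs["measures"] = list(self.measures)
            f.attrs["fixed_names"] = self.fixed_names
            f.attrs["patient_ids"] = [str(p) for p in self.patient_ids]


# ----------------------------------------------------------------------
def gibbs_fit(
    bundle: DesignBundle,
    priors: PriorSpec | None = None,
    settings: MCMCSettings | None = None,
    fix_D: np.ndarray | None = None,
    fix_Sigma: np.ndarray | None = None,
    store_random_effects: bool = True,
) -> MVLMMPosterior:
    """Fit the multivariate mixed model by Gibbs sampling.

    ``fix_D``/``fix_Sigma`` hold a covariance matrix fixed instead of
    sampling it (degenerate prior) — used for conjugate-oracle checks.
    Chains are reproducible given ``settings.seed``/``chain_seeds``.
    """
    priors = priors or PriorSpec()
    settings = settings or MCMCSettings()
    data = _prepare(bundle)
    nu_D, S_D, nu_S, S_S = priors.resolve(data.K * data.q, data.K)

    chains = []
    total_jitter = 0
    for seed in settings.seeds():
        rng = np.random.default_rng(seed)
        res = _run_chain(
            data, nu_D, S_D, nu_S, S_S, priors.v_beta, settings, rng,
            None if fix_D is None else np.asarray(fix_D, dtype=float),
            None if fix_Sigma is None else np.asarray(fix_Sigma, dtype=float),
            store_random_effects,
        )
        chains.append(res[:4])
        total_jitter += res[4]
    if total_jitter:
        warnings.warn(f"jitter applied {total_jitter} times during sampling", stacklevel=2)

    beta = np.stack([c[0] for c in chains])
    D = np.stack([c[1] for c in chains])
    Se = np.stack([c[2] for c in chains])
    b = np.stack([c[3] for c in chains]) if store_random_effects else None
    return MVLMMPosterior(
        beta=beta, D=D, Sigma_e=Se, b=b, measures=bundle.measures,
        fixed_names=[f"{m}:{n}" for m in bundle.measures for n in bundle.fixed_names],
        patient_ids=[p.patient_id for p in bundle.patients],
        settings=settings, n_jitter=total_jitter,
    )


# ----------------------------------------------------------------------
def psrf(chains: np.ndarray) -> float:
    """Gelman–Rubin potential scale reduction factor for one scalar.

    ``chains`` is (C, T) with C >= 2 chains of equal retained length.
    Values near 1 indicate convergence; > 1.1 is the conventional alarm.
    """
    c = np.asarray(chains, dtype=float)
    if c.ndim != 2 or c.shape[0] < 2:
        raise ValueError(
            "psrf needs >= 2 chains of equal length; split a single chain "
            "in half to use split-chain mode"
        )
    C, T = c.shape
    if T < 2:
        raise ValueError("chains must have length >= 2")
    means = c.mean(axis=1)
    W = c.var(axis=1, ddof=1).mean()
    B = T * means.var(ddof=1)
    if W == 0:
        return 1.0 if B == 0 else np.inf
    var_plus = (T - 1) / T * W + B / T
    return float(np.sqrt(var_plus / W))


def psrf_many(draws: np.ndarray) -> np.ndarray:
    """Vectorized PSRF over trailing parameter axes of (C, T, ...) draws."""
    c = np.asarray(draws, dtype=float)
    C, T = c.shape[:2]
    means = c.mean(axis=1)
    W = c.var(axis=1, ddof=1).mean(axis=0)
    B = T * means.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.sqrt(((T - 1) / T * W + B / T) / W)
    out = np.where(W == 0, np.where(B == 0, 1.0, np.inf), out)
    return out


def posterior_summary(post: MVLMMPosterior, include=("beta", "D", "Sigma_e")) -> pd.DataFrame:
    """Means, SDs, 95% credible intervals and PSRF per monitored scalar."""
    chains = post.monitored_chains(include)
    rows = []
    for name, c in chains.items():
        pooled = c.ravel()
        sd = float(pooled.std(ddof=1)) if pooled.size > 1 else np.nan
        rows.append(
            {
                "parameter": name,
                "mean": float(pooled.mean()),
                "sd": sd,
                "q2.5": float(np.quantile(pooled, 0.025)),
                "q97.5": float(np.quantile(pooled, 0.975)),
                "psrf": psrf(c) if c.shape[0] >= 2 and c.shape[1] >= 2 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")
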
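import warnings

import numpy as np
import pytest

from scleropred import BayesianMVLMM, MCMCSettings, SimulationSpec, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Two-measure cohort with warped marginals, modest size."""
    spec = SimulationSpec(m=30, measures=("pFVC", "pDLCO"), seed=42)
    ds, truth = simulate_cohort(spec)
    return ds, truth


@pytest.fixture(scope="session")
def fitted_small_model(small_cohort):
    """Short-chain fit of the small cohort, reused across test modules."""
    ds, truth = small_cohort
    model = BayesianMVLMM(
        settings=MCMCSettings(n_iter=800, burn_in=200, thin=2, n_chains=2, seed=7)
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(ds)
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
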
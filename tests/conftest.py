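import warnings

import pytest
from hypothesis import HealthCheck, settings

from screenprev import (
    LatentModelSpec,
    MCMCSpec,
    SimConfig,
    StratumSpec,
    fit_latent_model,
    simulate_population,
)

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

warnings.filterwarnings("ignore", message=".*ArviZ.*")


@pytest.fixture(scope="session")
def mixture_config() -> SimConfig:
    """Scaled-down mixture cohort: same structure as the full design."""
    return SimConfig(
        seed=2,
        stratum_specs=(
            StratumSpec("LR", 34_392, 1_500),
            StratumSpec("ER", 292, 292),
            StratumSpec("HR", 112, 112),
        ),
    )


@pytest.fixture(scope="session")
def mixture_cohort(mixture_config):
    return simulate_population(mixture_config)


@pytest.fixture(scope="session")
def quick_mcmc() -> MCMCSpec:
    """Reduced chains for unit tests; defaults stay at the full settings."""
    return MCMCSpec(n_chains=2, burn_in=800, iterations=1_500, seed=10)


@pytest.fixture(scope="session")
def mixture_draws(mixture_cohort, quick_mcmc):
    """One latent-model fit shared by the tests that only inspect draws."""
    return fit_latent_model(mixture_cohort, LatentModelSpec(), quick_mcmc)
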
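import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import brcapool as bp

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def paper_table() -> bp.CohortTable:
    return bp.paper_cohorts()


@pytest.fixture(scope="session")
def paper_fit(paper_table) -> bp.PosteriorDraws:
    """Default-length MCMC fit of the seven-cohort table, shared suite-wide."""
    return bp.run_mcmc(paper_table, config=bp.SamplerConfig(base_seed=20240901))


@pytest.fixture(scope="session")
def paper_grid(paper_table) -> bp.GridPosterior:
    """Default-resolution quadrature posterior of the seven-cohort table."""
    return bp.grid_posterior(paper_table)


@pytest.fixture(scope="session")
def paper_unadjusted(paper_table) -> list[bp.BetaPosterior]:
    return bp.unadjusted_posteriors(paper_table)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
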
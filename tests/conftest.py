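import numpy as np
import pytest

from mrpipe import SimulationConfig, simulate_cohort
from mrpipe.synthetic_cohort import ConfounderEffects, CostModel


@pytest.fixture(scope="session")
def desk_cohort():
    """One moderately sized cohort under the default generative model,
    shared across read-only tests."""
    return simulate_cohort(SimulationConfig.desk_scale(n=20_000, seed=11))


@pytest.fixture(scope="session")
def big_cohort():
    """Large cohort for moment checks that need tight Monte-Carlo error."""
    return simulate_cohort(SimulationConfig.desk_scale(n=100_000, seed=5))


def null_cost_config(n: int, seed: int, n_snps: int = 2) -> SimulationConfig:
    """Cost model with every causal, confounder and pleiotropic shift off:
    the marginal cost distribution is the pure zero-inflated lognormal."""
    zeros = np.zeros(n_snps)
    return SimulationConfig(
        n_individuals=n, n_snps=n_snps, seed=seed,
        liability_betas=zeros, csi_betas=zeros, risk_tolerance_betas=zeros,
        heaviness_snp=0,
        confounders=ConfounderEffects(0, 0, 0, 0, 0, 0),
        cost_model=CostModel(theta_init=0.0, theta_csi=0.0),
    )
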
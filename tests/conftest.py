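import numpy as np
import pytest

from prrr import (
    NonnegativePoissonRRR,
    PoissonRRR,
    SimulationSpec,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def gaussian_sim():
    """Small log-link dataset with known rank-3 truth."""
    return simulate_dataset(
        SimulationSpec(n_samples=200, n_covariates=10, n_genes=50, true_rank=3, seed=1)
    )


@pytest.fixture(scope="session")
def gaussian_model(gaussian_sim):
    return PoissonRRR(gaussian_sim.Y, gaussian_sim.X)


@pytest.fixture(scope="session")
def nonneg_sim():
    """Genotype-scheme dataset from the nonnegative generative model."""
    return simulate_dataset(
        SimulationSpec(
            n_samples=120,
            n_covariates=6,
            n_genes=20,
            true_rank=2,
            covariate_scheme="genotype",
            model="nnprrr",
            seed=7,
        )
    )


@pytest.fixture(scope="session")
def nonneg_model(nonneg_sim):
    return NonnegativePoissonRRR(nonneg_sim.Y, nonneg_sim.X)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
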
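import warnings

import numpy as np
import pytest

from mbhv import (
    FitConfig,
    SimulationScenario,
    center,
    fit_structured,
    simulate_grouped_dataset,
)


@pytest.fixture(scope="session")
def grouped_data():
    """A small grouped dataset (J=3, K=4, n=10) with real between-group shifts."""
    return simulate_grouped_dataset(
        SimulationScenario(n_dims=3, n_groups=4, n_per_group=10, between_var=2.0, seed=42),
        rep_index=0,
    )


@pytest.fixture(scope="session")
def centered_data(grouped_data):
    centered, transform = center(grouped_data)
    return centered, transform


@pytest.fixture(scope="session")
def fast_config():
    """Short chains adequate for a conjugate sampler on toy data."""
    return FitConfig(n_iterations=3_000, n_burnin=1_000, n_chains=2, thin=10, seed=7)


@pytest.fixture(scope="session")
def fitted_ensemble(centered_data, fast_config):
    centered, transform = centered_data
    return fit_structured(centered, fast_config, centering=transform)


@pytest.fixture
def grouped_csv(tmp_path, grouped_data):
    path = tmp_path / "grouped.csv"
    grouped_data.to_csv(path)
    return path


@pytest.fixture
def random_spd():
    """Factory for well-conditioned random SPD matrices."""

    def make(j, rng):
        a = rng.standard_normal((j, j))
        return a @ a.T + j * np.eye(j)

    return make
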
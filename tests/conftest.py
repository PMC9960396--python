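import numpy as np
import pandas as pd
import pytest

from phagedyn.synthetic import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The default study-condition community (50 species x 4 archetypes, 60 months)."""
    return simulate_dataset(SimulationConfig(), seed=1)


@pytest.fixture(scope="session")
def small_config():
    """A reduced community for fast pipeline-level tests."""
    return SimulationConfig(
        n_seasonal=8,
        n_persistent=8,
        n_occasional=8,
        n_sporadic=8,
        n_months=36,
        library_size_viral=20_000,
        library_size_cellular=5_000,
        n_coupled_hosts=4,
        n_uncoupled_hosts=2,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config, seed=7)


def dates_of(ds) -> pd.PeriodIndex:
    return pd.PeriodIndex(list(ds.counts_viral.samples), freq="M")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
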
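import numpy as np
import pandas as pd
import pytest

from pm25_dlnm import SimulationConfig, simulate_counts, simulate_environment


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A fast 400-day study (covers all four seasons) with the default surface."""
    return SimulationConfig(n_days=400, seed=7)


@pytest.fixture(scope="session")
def small_env(small_config) -> pd.DataFrame:
    return simulate_environment(small_config)


@pytest.fixture(scope="session")
def small_counts(small_config, small_env) -> pd.DataFrame:
    return simulate_counts(small_env, small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
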
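import numpy as np
import pytest

from omzox.simulate import SimulationConfig, simulate_bottle


@pytest.fixture(scope="session")
def scm_like_config() -> SimulationConfig:
    """A secondary-chlorophyll-maximum-like bottle: sub-uM DO, active
    nitrite oxidation fed by nitrate reduction, modest heterotrophy."""
    return SimulationConfig(
        initial_O2=480.0,
        initial_NH4=100.0,
        initial_NO2=2000.0,
        initial_NO3=20_000.0,
        R_AO=10.0,
        vmax_NO=149.0,
        Km_NO=63.8,
        vmax_het=300.0,
        Km_het=1804.0,
        R_NAR=60.0,
        duration=24.0,
        dt=0.01,
    )


@pytest.fixture(scope="session")
def scm_like_series(scm_like_config):
    return simulate_bottle(scm_like_config)


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_901)
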
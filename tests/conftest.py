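import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from msnp.io import load_pyro_rs36221701
from msnp.ras import compute_probe_stats
from msnp.simulate import SimulationConfig, simulate_intensities, simulate_panel

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

PANEL_SEED = 1


@pytest.fixture(scope="session")
def pyro_table() -> pd.DataFrame:
    return load_pyro_rs36221701()


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=PANEL_SEED)


@pytest.fixture(scope="session")
def panel(default_config):
    return simulate_panel(default_config)


@pytest.fixture(scope="session")
def panel_intensities(panel, default_config):
    return simulate_intensities(
        panel.probes, panel.truth, panel.genotypes, default_config
    )


@pytest.fixture(scope="session")
def panel_stats(panel, panel_intensities):
    """(stats, het_shifts) of the default synthetic panel."""
    return compute_probe_stats(panel_intensities, panel.genotypes)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
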
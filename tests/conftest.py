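import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mriv import builtin_presets, simulate_dataset

settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def sim2():
    return builtin_presets()["sim2"]


@pytest.fixture(scope="session")
def sim1():
    return builtin_presets()["sim1"]


@pytest.fixture(scope="session")
def sim2_dataset(sim2):
    """One fixed draw of the four-SNP weak/strong-instrument design."""
    return simulate_dataset(sim2, 42)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
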
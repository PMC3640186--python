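import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from landuse16s.simulate import SimulationConfig, generate_reference_db

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(seed=11, n_genera=6, n_samples_per_group=4, reads_per_sample=60)


@pytest.fixture(scope="session")
def small_db(small_config):
    return generate_reference_db(small_config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)
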
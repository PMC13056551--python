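import numpy as np
import pytest

from airway_resistome.synthetic_data import SimConfig, simulate_all


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(n_patients=40, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return simulate_all(small_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
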
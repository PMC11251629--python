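import numpy as np
import pytest

from emgforge import SimConfig, MuscleModel, PoolConfig
from emgforge.muap import ConditionVector


@pytest.fixture
def cfg() -> SimConfig:
    return SimConfig()


@pytest.fixture
def small_muscle() -> MuscleModel:
    """A 10-unit flexor for fast pool tests."""
    return MuscleModel(
        "testflex", 0.063, 0.244, 74.0,
        {"wrist_flexion": 0.015}, territory_centre_depth=7.0,
        territory_radius=4.0, ml_angle=270.0, n_units=10, total_fibres=2000)


@pytest.fixture
def pool_config() -> PoolConfig:
    return PoolConfig()


@pytest.fixture
def midrange_condition() -> ConditionVector:
    return ConditionVector(fat_conductivity=0.5, fibre_number=0.5, depth=0.5,
                           ml_pos=0.5, iz_pos=0.5, cv=0.5, fibre_length=0.5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
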
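import numpy as np
import pytest

from sacchsim.engine import TrainConfig
from sacchsim.kinetics import KineticParameters
from sacchsim.partition import PartitionParameters


@pytest.fixture(scope="session")
def kp() -> KineticParameters:
    return KineticParameters()


@pytest.fixture(scope="session")
def pp() -> PartitionParameters:
    return PartitionParameters()


@pytest.fixture(scope="session")
def train2_cfg() -> TrainConfig:
    """The 5 mg/g validation train (package defaults)."""
    return TrainConfig()


@pytest.fixture(scope="session")
def train1_cfg(train2_cfg) -> TrainConfig:
    """The 2 mg/g validation train."""
    return train2_cfg.replace(enzyme_loading_mg_per_g=2.0, enzyme_stage=4,
                              wet_cake_target_g=85.0, operation_days=24.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
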
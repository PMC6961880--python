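import numpy as np
import pytest

from whealsim.kinetics import SET_I, KineticParams
from whealsim.rdsolver import SolverConfig, WhealParams


@pytest.fixture(scope="session")
def set_i() -> KineticParams:
    return SET_I


@pytest.fixture(scope="session")
def wheal() -> WhealParams:
    return WhealParams()


@pytest.fixture()
def small_cfg() -> SolverConfig:
    """Coarse 2-D grid for fast kinetic-dominated tests."""
    return SolverConfig(grid_n=32, t_end=4.0, snapshot_interval=0.5)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20231107)
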
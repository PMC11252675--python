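import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from iceprop.biophysics import CellParams, CoolingProtocol
from iceprop.markov import two_by_two_graph

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def hepatocyte() -> CellParams:
    return CellParams.rat_hepatocyte()


@pytest.fixture(scope="session")
def protocol_fast() -> CoolingProtocol:
    """Rapid-cooling protocol (400 K/min) to the packaged -15 C endpoint."""
    return CoolingProtocol(T0=272.15, B=400.0, T_end=258.15)


@pytest.fixture(scope="session")
def protocol_moderate() -> CoolingProtocol:
    return CoolingProtocol(T0=272.15, B=100.0, T_end=258.15)


@pytest.fixture(scope="session")
def square4():
    """The packaged 2x2 construct: complete graph on 4 cells, dihedral symmetry."""
    return two_by_two_graph()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240717)
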
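import numpy as np
import pytest

from ordfit.data import RegionMap, packaged_fixture
from ordfit.model import GermariumModel, core_topology, default_parameters
from ordfit.synth import default_study


@pytest.fixture(scope="session")
def region_map():
    return RegionMap()


@pytest.fixture(scope="session")
def fixture_set():
    return packaged_fixture()


@pytest.fixture(scope="session")
def core_model():
    topo = core_topology()
    return GermariumModel(topo, default_parameters(topo))


@pytest.fixture(scope="session")
def study():
    """Noiseless two-regulator synthetic study (shared; treat as read-only)."""
    return default_study(rank_noise=0.0, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
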
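import numpy as np
import pytest

from gcmodel import (
    CellProfile,
    TraffickingParams,
    build_network,
    default_rate_table,
)


@pytest.fixture(scope="session")
def rates():
    return default_rate_table()


@pytest.fixture(scope="session")
def traffic():
    return TraffickingParams()


@pytest.fixture(scope="session")
def il2_network():
    return build_network({"IL2"})


@pytest.fixture(scope="session")
def full_network():
    return build_network(("IL2", "IL15", "IL4", "IL7", "IL9", "IL21"))


@pytest.fixture(scope="session")
def treg():
    return CellProfile("Treg", receptor_surface={"IL2Ra": 3000, "IL2Rb": 700, "gc": 3000})


@pytest.fixture(scope="session")
def nk():
    return CellProfile("NK", receptor_surface={"IL2Ra": 50, "IL2Rb": 5000, "gc": 800})


@pytest.fixture(scope="session")
def thelper():
    return CellProfile("Thelper",
                       receptor_surface={"IL7Ra": 2000, "IL4Ra": 1000, "gc": 2500})


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
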
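import numpy as np
import pytest

from molperceive import fixtures as fx
from molperceive.bond_perception import perceive_covalent_bonds
from molperceive.config import PerceptionConfig


@pytest.fixture
def cfg():
    return PerceptionConfig()


def _bonded(builder):
    system = builder()
    return perceive_covalent_bonds(system)


@pytest.fixture
def water():
    return _bonded(fx.water)


@pytest.fixture
def methane():
    return _bonded(fx.methane)


@pytest.fixture
def benzene():
    return _bonded(fx.benzene)


@pytest.fixture
def biphenyl():
    return _bonded(fx.biphenyl)


@pytest.fixture
def naphthalene():
    return _bonded(fx.naphthalene)


@pytest.fixture
def celecoxib():
    return _bonded(fx.celecoxib)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
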
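import numpy as np
import pytest

from coughsim.mechanics import MechanicsModel
from coughsim.params import FreeParameters, build_abdominal_geometry, derive_parameters


@pytest.fixture(scope="session")
def free():
    return FreeParameters()


@pytest.fixture(scope="session")
def geom(free):
    return build_abdominal_geometry(free.c_t)


@pytest.fixture(scope="session")
def derived(free, geom):
    return derive_parameters(free, geom)


@pytest.fixture(scope="session")
def model(free, geom, derived):
    return MechanicsModel(free=free, derived=derived, geom=geom)


@pytest.fixture(scope="session")
def equilibrium(model):
    return model.passive_equilibrium()
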
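import numpy as np
import pytest

from coverdyn.ipm import Mesh
from coverdyn.params import VitalRateParams
from coverdyn.synth import default_generating_params, generate_worked_fixture


@pytest.fixture(scope="session")
def worked_fixture():
    """Hand-written two-plot survey with enumerable transitions."""
    records, params = generate_worked_fixture()
    return records


@pytest.fixture(scope="session")
def default_params():
    return default_generating_params()


@pytest.fixture
def small_mesh():
    return Mesh(m=12)


@pytest.fixture
def decoupled_params():
    """One vital-rate set with no abundance dependence at all (cross and
    self coefficients zero), so groups evolve independently."""
    p = VitalRateParams(
        persistence=[1.5, 0.2, 0.0, 0.0, 0.0, 0.0],
        expansion_mean=[0.7, 0.6, 0.0, 0.0, 0.0, 0.0],
        expansion_sd=[0.4, 0.0, 0.0, 0.0, 0.0, 0.0],
        colonisation_mean=[0.8, 0.0, 0.0, 0.0],
        colonisation_sd=[0.5, 0.0, 0.0, 0.0],
        col_rate=0.5)
    return {g: p for g in ("grass", "legume", "forb")}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160614)
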
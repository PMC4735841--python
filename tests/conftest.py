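import numpy as np
import pytest

import comptel
from comptel import simulator
from comptel.config import make_fixture


@pytest.fixture(scope="session")
def geometry():
    return comptel.default_prototype()


@pytest.fixture(scope="session")
def attenuation():
    return comptel.labr3_attenuation()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def noise_free_triples():
    """Correctly ordered 1275 keV triples with ideal response (truth coords)."""
    tr = make_fixture("noise_free_triples", {"n_photons": 90_000_000}, seed=5)
    assert len(tr) >= 10, "fixture produced too few noise-free triples"
    return tr


@pytest.fixture(scope="session")
def na22_source():
    return simulator.default_na22_source()
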
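import numpy as np
import pytest

from rptdose.attenuation import build_table
from rptdose.nuclide import load_i131
from rptdose.phantom import PhantomConfig, build_phantom


@pytest.fixture(scope="session")
def xs_table():
    return build_table()


@pytest.fixture(scope="session")
def i131():
    return load_i131()


@pytest.fixture(scope="session")
def geometry():
    return build_phantom(PhantomConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
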
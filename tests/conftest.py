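import numpy as np
import pytest
from hypothesis import settings

from flavotune.surface import generate_surface
from flavotune.synthetic import make_delta_charges, make_toy_flavin

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_flavin():
    return make_toy_flavin()


@pytest.fixture(scope="session")
def delta_s1(toy_flavin):
    return make_delta_charges("S1_pipi", toy_flavin)


@pytest.fixture(scope="session")
def delta_tn(toy_flavin):
    return make_delta_charges("Tn_npi", toy_flavin)


@pytest.fixture(scope="session")
def cloud_k2(toy_flavin):
    return generate_surface(toy_flavin, scale=2.0, density=1.0)


@pytest.fixture(scope="session")
def cloud_k1(toy_flavin):
    return generate_surface(toy_flavin, scale=1.0, density=1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
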
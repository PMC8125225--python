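import numpy as np
import pytest
from hypothesis import settings

from pulsekin import KineticScheme, RateConstantSet, build_default_library

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def library():
    """Default five-component library on the 270-700 nm, 2 nm grid."""
    return build_default_library()


@pytest.fixture
def scheme():
    return KineticScheme()


@pytest.fixture
def rates():
    return RateConstantSet()


@pytest.fixture
def rng():
    return np.random.default_rng(20210430)
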
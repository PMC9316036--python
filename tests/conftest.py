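import numpy as np
import pytest

from nadtherm.io import fixture_path, read_rate_table, to_measurements
from nadtherm.network import EnzymeProfile, build_default_model


@pytest.fixture(scope="session")
def model():
    return build_default_model()


@pytest.fixture(scope="session")
def measurements():
    return to_measurements(read_rate_table(fixture_path()))


@pytest.fixture(scope="session")
def rate_table():
    return read_rate_table(fixture_path())


@pytest.fixture
def uniform_profile():
    return EnzymeProfile.uniform(100.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
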
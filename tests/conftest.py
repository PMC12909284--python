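import numpy as np
import pytest

from gsoelm import TODDLER_SCHEMA, sample_table_fixture


@pytest.fixture(scope="session")
def sample_table():
    return sample_table_fixture()


@pytest.fixture(scope="session")
def toddler_schema():
    return TODDLER_SCHEMA


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
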
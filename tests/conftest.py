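import numpy as np
import pytest
from hypothesis import settings

from rosettasim.curves import default_function_set

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fs():
    return default_function_set()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
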
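import numpy as np
import pytest
from hypothesis import settings

import opalstar as op

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def rich2():
    return op.make_environment("rich", 2)


@pytest.fixture
def lean2():
    return op.make_environment("lean", 2)
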
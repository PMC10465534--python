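import numpy as np
import pytest

from starkit.model import DEFAULT_PARAMS


@pytest.fixture
def params():
    return DEFAULT_PARAMS


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
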
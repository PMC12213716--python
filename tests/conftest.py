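import numpy as np
import pytest

from fieldbridge import DegradationParams, make_high_field_subject


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def phantom64():
    return make_high_field_subject("s1", 4, 64, "A", seed=7)


@pytest.fixture
def phantom_slice():
    return make_high_field_subject("s1", 1, 64, "A", seed=7).slices[0]


@pytest.fixture
def neutral_params():
    return DegradationParams.neutral(seed=11)
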
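import numpy as np
import pytest

from entrokit import FixtureSpec, TimeSeries, generate


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def gaussian_100():
    return generate(FixtureSpec("gaussian_noise", 100, seed=7))


@pytest.fixture
def alternating_8():
    return TimeSeries([1.0, 2.0, 1.0, 2.0, 1.0, 2.0, 1.0, 2.0])
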
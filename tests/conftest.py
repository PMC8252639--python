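import numpy as np
import pytest

from srchain import ChainSpec, PolicySpec


@pytest.fixture
def spec():
    """Default chain: 10 states, reward 1, gamma 0.97, no punishment."""
    return ChainSpec()


@pytest.fixture
def punished_spec():
    """Chain with the post-goal punishment state delivering -2."""
    return ChainSpec(has_punishment=True, punishment_size=-2.0)


@pytest.fixture
def resistant():
    return PolicySpec.resistant(0.75)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
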
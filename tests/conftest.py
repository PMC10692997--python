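import numpy as np
import pytest

from pleiosim import EnvironmentSpec, ModelParams


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture
def small_params():
    return ModelParams(N=50, n_traits=4, n_a=4)


@pytest.fixture
def default_env():
    return EnvironmentSpec(pattern="correlated")
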
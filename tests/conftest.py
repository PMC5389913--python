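import numpy as np
import pytest

from metalcg.params import load_metal_params


@pytest.fixture(scope="session")
def metal_params():
    return load_metal_params()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250925)


@pytest.fixture()
def fresh_rng():
    return np.random.default_rng(424242)
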
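import numpy as np
import pytest

from hgscreen import simulate


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def substrate_windows():
    return simulate.substrate_windows()


@pytest.fixture
def toy_pfm():
    return simulate.example_pfm()


@pytest.fixture
def default_spec():
    return simulate.GeneratorSpec(seed=7)
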
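import numpy as np
import pytest

from ionslab.materials import ALUMINUM, POLYETHYLENE, WATER


@pytest.fixture
def water():
    return WATER


@pytest.fixture
def polyethylene():
    return POLYETHYLENE


@pytest.fixture
def aluminum():
    return ALUMINUM


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
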
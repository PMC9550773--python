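import numpy as np
import pytest

from hierpc.paradigm import build_design, default_designs


@pytest.fixture(scope="session")
def block1():
    """The published Block 1 configuration: 2-tone, 96/24/24."""
    return build_design("B1", 2, {"xx": 96, "xy": 24, "xo": 24})


@pytest.fixture(scope="session")
def designs8():
    """The canonical 8-block grid."""
    return default_designs()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
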
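import numpy as np
import pytest

from junctiontrack.io_tables import Rect


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def roi_4um():
    return Rect(0.0, 0.0, 4000.0, 4000.0)


@pytest.fixture
def roi_small():
    return Rect(0.0, 0.0, 1000.0, 1000.0)
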
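import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def unit_square_outline():
    from lignoquant.io_core import Outline

    return Outline("square", np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]))


@pytest.fixture
def l_shape_outline():
    from lignoquant.io_core import Outline

    return Outline(
        "L",
        np.array([[0.0, 0.0], [2.0, 0.0], [2.0, 1.0], [1.0, 1.0], [1.0, 2.0], [0.0, 2.0]]),
    )
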
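import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make the oracles module importable


@pytest.fixture
def rng():
    return np.random.default_rng(20240214)


@pytest.fixture
def random_mask(rng):
    def _make(shape=(16, 16), p=0.5):
        return (rng.random(shape) < p).astype(np.uint8)

    return _make
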
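import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_image(rng, shape=(16, 16)):
    return rng.integers(0, 256, size=shape).astype(np.uint8)


@pytest.fixture
def image_pair(rng):
    a = random_image(rng)
    noise = rng.integers(-20, 21, size=a.shape)
    b = np.clip(a.astype(int) + noise, 0, 255).astype(np.uint8)
    return a, b
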
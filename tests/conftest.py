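import numpy as np
import pytest

from vegmorph import BinaryPattern


@pytest.fixture
def rng():
    return np.random.default_rng(20170215)


@pytest.fixture
def random_small_masks(rng):
    """Seeded random masks whose foreground graphs have <= ~100 vertices."""
    masks = []
    for _ in range(25):
        shape = (rng.integers(4, 11), rng.integers(4, 11))
        mask = rng.random(shape) < rng.uniform(0.2, 0.8)
        if not mask.any():
            mask[0, 0] = True
        masks.append(BinaryPattern(mask))
    return masks
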
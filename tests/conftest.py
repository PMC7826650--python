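import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def random_levels(rng):
    """Small random discretised ROI volumes with an irregular mask."""

    def make(shape=(4, 4, 4), n_levels=3, roi_frac=0.8):
        levels = rng.integers(1, n_levels + 1, size=shape)
        mask = rng.random(shape) < roi_frac
        if not mask.any():
            mask.flat[0] = True
        return np.where(mask, levels, 0).astype(np.int64)

    return make
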
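import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make _oracles importable

from karsthealth import LandUseRaster, SyntheticScenario


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_scenario():
    """Desk-scale scenario: 3×3 zone lattice, 2 epochs, 30×30 cells."""
    return SyntheticScenario(
        grid_shape=(30, 30), n_zones=9, years=(2000, 2005), autocorr_range=3, seed=11
    )


@pytest.fixture
def random_raster(rng):
    def make(shape=(12, 12), n_classes=3, nodata=255, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        return LandUseRaster(r.integers(1, n_classes + 1, size=shape), nodata=nodata)

    return make
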
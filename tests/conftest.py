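import numpy as np
import pytest

from fragtrack import BinaryLandscape


@pytest.fixture
def random_landscape():
    """Factory for random binary landscapes at 30 m resolution."""

    def make(rows=40, cols=40, p_forest=0.6, seed=0, pixel_size=30.0):
        rng = np.random.default_rng(seed)
        values = (rng.random((rows, cols)) < p_forest).astype(np.int8)
        return BinaryLandscape(values, pixel_size=pixel_size,
                               origin=(0.0, rows * pixel_size), epoch_year=2000)

    return make


@pytest.fixture
def clumped_landscape():
    """Factory for spatially clumped landscapes (smoothed noise), which
    exercise holes and core tracts more realistically than iid noise."""

    def make(rows=40, cols=40, p_forest=0.6, seed=0, pixel_size=30.0, smooth=2):
        from scipy import ndimage

        rng = np.random.default_rng(seed)
        field = ndimage.uniform_filter(rng.random((rows, cols)), size=2 * smooth + 1)
        thresh = np.quantile(field, 1 - p_forest)
        values = (field >= thresh).astype(np.int8)
        return BinaryLandscape(values, pixel_size=pixel_size,
                               origin=(0.0, rows * pixel_size), epoch_year=2000)

    return make
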
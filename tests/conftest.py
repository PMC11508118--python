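import numpy as np
import pytest

from inunscore.raster import RasterGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_grid(values, cell_size=1.0, nodata_mask=None):
    return RasterGrid(np.asarray(values, dtype=float), cell_size=cell_size,
                      nodata_mask=nodata_mask)


@pytest.fixture
def south_plane():
    """6x4 plane tilted down toward the south (row 0 highest)."""
    vals = np.tile(np.arange(6, 0, -1, dtype=float)[:, None], (1, 4))
    return RasterGrid(vals, cell_size=1.0)
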
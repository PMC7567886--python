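import numpy as np
import pytest

from histoscape.points import PointPattern, Window
from histoscape.raster import CategoricalRaster


@pytest.fixture
def unit_window():
    return Window(0.0, 1.0, 0.0, 1.0)


@pytest.fixture
def checkerboard():
    return CategoricalRaster(np.array([[1, 2], [2, 1]]))


@pytest.fixture
def three_quarters():
    return CategoricalRaster(np.array([[1, 1], [1, 2]]))


def random_raster(rng, shape=(5, 5), n_classes=3, nodata_frac=0.0):
    values = rng.integers(1, n_classes + 1, size=shape)
    nodata = None
    if nodata_frac > 0:
        nodata = 0
        mask = rng.uniform(size=shape) < nodata_frac
        values[mask] = 0
        if (values != 0).sum() == 0:
            values[0, 0] = 1
    return CategoricalRaster(values, nodata_code=nodata)


def random_pattern(rng, n, window):
    pts = np.column_stack([rng.uniform(window.x_min, window.x_max, n),
                           rng.uniform(window.y_min, window.y_max, n)])
    return PointPattern(pts, window)
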
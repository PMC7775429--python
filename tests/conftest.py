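import numpy as np
import pytest

from gridveg import GridSpec, TimeAxis, ClimateCube, ClassRaster


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def grid3():
    return GridSpec(3, 3, 1.0)


@pytest.fixture
def monthly_cube_factory():
    """Build a monthly cube from an array of (n_months, rows, cols)."""

    def build(values, start_year=2000, start_month=1, product="p", variable="v",
              cell_size=1.0, valid_mask=None):
        values = np.asarray(values, dtype=float)
        grid = GridSpec(values.shape[1], values.shape[2], cell_size)
        time = TimeAxis.monthly(start_year, start_month, values.shape[0])
        return ClimateCube(product, variable, grid, time, values, valid_mask)

    return build


@pytest.fixture
def class_raster3():
    """3x3 raster with 4 non-vegetated pixels and 5 vegetated ones."""
    ids = np.array([
        [3, 0, 3],
        [1, 2, 1],
        [3, 2, 3],
    ])
    return ClassRaster(GridSpec(3, 3, 1.0), ids)
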
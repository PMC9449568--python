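import numpy as np
import pytest

from ensdm.geodata_io import (
    GridTransform,
    OccurrenceSet,
    PredictorStack,
    RasterGrid,
    WGS84,
)


@pytest.fixture
def transform():
    """A 0.1-degree grid with its north-west corner at (30 E, 5 N)."""
    return GridTransform(west=30.0, north=5.0, dx=0.1, dy=-0.1)


@pytest.fixture
def small_grid(transform):
    """5x5 grid of counting values, no nodata."""
    values = np.arange(25, dtype=float).reshape(5, 5)
    return RasterGrid(values, transform, WGS84, np.zeros((5, 5), bool))


@pytest.fixture
def small_stack(transform):
    """Two co-registered 5x5 layers named a and b."""
    a = RasterGrid(np.arange(25, dtype=float).reshape(5, 5), transform)
    b = RasterGrid(np.ones((5, 5)), transform)
    return PredictorStack({"a": a, "b": b})


@pytest.fixture
def separable_table():
    """Linearly separable 2-feature classification fixture (n=60)."""
    import pandas as pd
    from ensdm.predictors import FeatureTable

    rng = np.random.default_rng(7)
    n = 30
    x_pos = rng.normal(2.0, 0.3, size=(n, 2))
    x_neg = rng.normal(-2.0, 0.3, size=(n, 2))
    X = pd.DataFrame(np.vstack([x_pos, x_neg]), columns=["f1", "f2"])
    y = np.array([1] * n + [0] * n)
    return FeatureTable(X, y)


def grid_from(values, transform, mask=None):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.zeros(values.shape, bool)
    return RasterGrid(values, transform, WGS84, np.asarray(mask, bool))


@pytest.fixture
def points_on(transform):
    """Factory: OccurrenceSet at the centres of given (row, col) cells."""

    def make(cells, label=1):
        lons, lats = [], []
        for r, c in cells:
            lon, lat = transform.cell_center(r, c)
            lons.append(lon)
            lats.append(lat)
        return OccurrenceSet.from_arrays(lons, lats, label=label)

    return make
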
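import numpy as np
import pytest

from coastsdm.grid import RasterGrid


def make_grid(values, cell=460.0, crs="EPSG:32633", mask=None):
    """Small helper: north-up grid with the given cell size in meters."""
    values = np.asarray(values, dtype=float)
    nr, _nc = values.shape
    transform = (0.0, cell, 0.0, nr * cell, 0.0, -cell)
    return RasterGrid(values, transform, crs, mask)


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study shared by read-only tests."""
    from coastsdm.landscape import simulate_study

    return simulate_study(seed=0)
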
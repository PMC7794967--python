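import numpy as np
import pytest

from karsthealth.grid import build_fishnet
from karsthealth.raster import LANDUSE_LEGEND, Raster
from karsthealth.scene import SceneParams, generate_scene


def make_landuse(codes, cell_size=1000.0, x0=0.0, y1=None):
    """Categorical raster from a 2-D code array, NW origin at (x0, y1)."""
    codes = np.asarray(codes, dtype=np.int64)
    if y1 is None:
        y1 = codes.shape[0] * cell_size
    return Raster(codes, x_origin=x0, y_origin=y1, cell_size=cell_size,
                  nodata=0, legend=LANDUSE_LEGEND)


def make_continuous(values, cell_size=1000.0, x0=0.0, y1=None):
    values = np.asarray(values, dtype=float)
    if y1 is None:
        y1 = values.shape[0] * cell_size
    return Raster(values, x_origin=x0, y_origin=y1, cell_size=cell_size,
                  nodata=-9999.0)


@pytest.fixture(scope="session")
def small_scene():
    """A 20 km x 20 km three-epoch scene shared by fast tests."""
    params = SceneParams(
        extent=(0.0, 0.0, 20_000.0, 20_000.0),
        epochs=[1990, 2000, 2010],
        n_urban_centers=1,
        n_mines=12,
        n_patch_nuclei=40,
        seed=11,
    )
    return generate_scene(params)


@pytest.fixture
def grid_4km():
    """2x2 fishnet of 2 km cells over a 4 km square."""
    return build_fishnet((0.0, 0.0, 4000.0, 4000.0), 2000.0)
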
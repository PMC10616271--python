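import numpy as np
import pandas as pd
import pytest

from landclim.rasters import CategoricalRaster
from landclim.synth import SyntheticConfig, generate_world


@pytest.fixture(scope="session")
def small_world():
    """A small but complete synthetic world shared across test modules."""
    cfg = SyntheticConfig(seed=7, n_squares_x=12, n_squares_y=12,
                          fine_per_square=6)
    return generate_world(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def toy_raster_pair():
    """4x4 rasters, one square of 4x4 pixels, with a known pixel fate."""
    hist = CategoricalRaster(np.array([[2, 2, 2, 2],
                                       [2, 2, 2, 2],
                                       [3, 3, 4, 4],
                                       [3, 3, 4, 4]]), resolution=1.0)
    mod = CategoricalRaster(np.array([[6, 6, 2, 2],
                                      [6, 2, 2, 2],
                                      [3, 3, 4, 4],
                                      [3, 1, 4, 4]]), resolution=1.0)
    return hist, mod


def species_frame(world, species_id):
    """Truth-based modelling frame for one species of a synthetic world."""
    tab = world.square_table
    occ1 = world.occupancy[1][species_id].astype(bool)
    y = world.occupancy[2][species_id][occ1].to_numpy(float)
    data = pd.DataFrame({
        "land_conversion": tab.loc[occ1, "z_L"],
        "temperature_trend": tab.loc[occ1, "z_T"],
        "effort": tab.loc[occ1, "z_E"],
        "microclimate": tab.loc[occ1, "z_M"],
    })
    import zlib
    rng_local = np.random.default_rng(zlib.crc32(species_id.encode()) % (2 ** 31))
    data["pcnm1"] = rng_local.normal(0, 0.05, len(data))
    data["pcnm2"] = rng_local.normal(0, 0.05, len(data))
    return data, y
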
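import numpy as np
import pytest

from abaclim import (GridGeometry, RasterGrid, SyntheticTruth,
                     generate_baseline, generate_surveys, study_domain)


@pytest.fixture(scope="session")
def truth():
    return SyntheticTruth()


@pytest.fixture(scope="session")
def domain():
    return study_domain()


@pytest.fixture(scope="session")
def baseline_august(domain, truth):
    return generate_baseline(domain, "august", truth, noise_sd=0.3, seed=1)


@pytest.fixture(scope="session")
def baseline_march(domain, truth):
    return generate_baseline(domain, "march", truth, noise_sd=0.3, seed=2)


@pytest.fixture(scope="session")
def surveys_B(baseline_august, truth):
    return generate_surveys(baseline_august, truth, n_records=2000,
                            species="B", seed=7)


@pytest.fixture
def small_grid():
    geom = GridGeometry(n_lat=10, n_lon=10, lon_origin=131.0,
                        lat_origin=-36.0, resolution=0.1)
    return RasterGrid(values=np.full((10, 10), 3.0), geometry=geom,
                      variable="test")


def make_grid(values, resolution=0.1, lon_origin=131.0, lat_origin=-36.0,
              mask=None):
    values = np.asarray(values, dtype=float)
    geom = GridGeometry(n_lat=values.shape[0], n_lon=values.shape[1],
                        lon_origin=lon_origin, lat_origin=lat_origin,
                        resolution=resolution)
    return RasterGrid(values=values, geometry=geom, mask=mask)
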
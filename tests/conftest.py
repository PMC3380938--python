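import numpy as np
import pandas as pd
import pytest

from lgcpindex import GridSpec, ModelParams


@pytest.fixture
def small_grid():
    return GridSpec(lat0=53.0, lon0=0.0, dlat=0.3, dlon=0.6, nlat=4, nlon=4)


@pytest.fixture
def tiny_grid():
    return GridSpec(lat0=54.0, lon0=2.0, dlat=0.3, dlon=0.6, nlat=2, nlon=2)


@pytest.fixture
def table1_params():
    """Published survey parameter estimates (decays, quadratics, variances)."""
    return ModelParams(sigma0_sq=2.36, sigma_sq=6.43, sigma_y_sq=1.0,
                       log_alpha=-5.45, log_beta=-1.22,
                       a_spawn1=2.41e-1, a_spawn2=6.21e-4,
                       a_thc1=8.33e-2, a_thc2=2.71e-3)


def make_samples(n, grid, years, rng, counts=None, thc=20.0):
    """Hand-rolled valid sample table inside ``grid``."""
    year_arr = rng.integers(years[0], years[1] + 1, n)
    df = pd.DataFrame({
        "sample_id": [f"t{i:05d}" for i in range(n)],
        "lat": rng.uniform(grid.lat0, grid.lat_max - 1e-9, n),
        "lon": rng.uniform(grid.lon0, grid.lon_max - 1e-9, n),
        "year": year_arr,
        "day_of_year": rng.integers(100, 260, n),
        "hour": rng.integers(0, 24, n),
        "count": counts if counts is not None else rng.poisson(1.0, n),
        "thermocline_depth_m": np.full(n, float(thc)),
    })
    return df


@pytest.fixture
def sample_factory():
    return make_samples
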
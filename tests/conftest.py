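import numpy as np
import pytest

from aodpm25.grid import GridSpec
from aodpm25.synthetic import MetConfig, TruthConfig, default_dates, simulate_fixture


@pytest.fixture(scope="session")
def small_grid():
    return GridSpec(lat0=21.3, lon0=74.4, n_lat=20, n_lon=24, cell=0.03)


@pytest.fixture(scope="session")
def fixture_bundle(small_grid):
    """Default-noise bundle at reduced scale (120 days) for module tests."""
    return simulate_fixture(small_grid, default_dates(2018, 120), TruthConfig(seed=7))


def noiseless_truth(seed: int = 3, **overrides) -> TruthConfig:
    """All stochastic terms off: data satisfy every model stage exactly."""
    kw = dict(link_noise_sd=0.0, sigma_eps=0.0, eps_spatial_sd=0.0, re_sd=(0.0,) * 6,
              b1_amplitude=0.0, monitor_noise_sd=0.0, outlier_rate=0.0, seed=seed)
    kw.update(overrides)
    return TruthConfig(**kw)


@pytest.fixture(scope="session")
def noiseless_bundle(small_grid):
    return simulate_fixture(small_grid, default_dates(2018, 60), noiseless_truth())


@pytest.fixture(scope="session")
def analysis_table(fixture_bundle):
    """Collocated, screened analysis table for the default-noise bundle."""
    from aodpm25 import integrate, stage1

    b = fixture_bundle
    coeffs = stage1.fit_gridwise_regression(b.aod.satellite, b.aod.reanalysis)
    final, prov = stage1.impute_aod(b.aod.satellite, b.aod.reanalysis, coeffs)
    static = {"urban": b.static.urban, "grass": b.static.grass}
    table = integrate.collocate(b.monitors, final, prov, b.met, static)
    table, _ = integrate.screen_extremes(table)
    return table
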
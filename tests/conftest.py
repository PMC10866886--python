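import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from wfcrop.pipeline import run_pipeline
from wfcrop.soil_water import TEXTURE_CLASSES, SoilProfile, SoilState
from wfcrop.synthetic_world import WorldConfig, generate_world

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def loam():
    return TEXTURE_CLASSES["loam"]


@pytest.fixture(scope="session")
def deep_profile():
    return SoilProfile.deep()


@pytest.fixture()
def fc_state(deep_profile, loam):
    return SoilState.at_content(deep_profile, loam)


@pytest.fixture(scope="session")
def small_config():
    return WorldConfig(seed=7, years=5, coarse_rows=2, coarse_cols=2,
                       fine_factor=2, n_countries=2)


@pytest.fixture(scope="session")
def small_world(small_config):
    return generate_world(small_config)


@pytest.fixture(scope="session")
def default_pipeline():
    """One full run of the default study conditions (4x4 coarse grid,
    3 countries, 5 archetype crops, 12 years), shared across tests."""
    return run_pipeline(WorldConfig(seed=11))


@pytest.fixture(scope="session")
def humid_world():
    """Single humid coarse cell, for warm-up and conservation checks."""
    from wfcrop.synthetic_world import ClimateParams
    cfg = WorldConfig(seed=5, years=4, coarse_rows=1, coarse_cols=1,
                      fine_factor=1, n_countries=1,
                      climates=(ClimateParams(1600.0, 0.45, 22.0, 4.0,
                                              2.0, 78.0, 12.0),))
    return generate_world(cfg)


def make_constant_weather(config, tmean=20.0, amplitude=8.0, precip_every=4,
                          precip_mm=12.0, delta_t=0.0):
    """Deterministic weather: exact sinusoidal annual cycle, periodic rain.

    Used where tests need a 'mean climate' with no stochastic variability.
    """
    from wfcrop.synthetic_world import DAYS_PER_YEAR, WeatherSeries
    n = config.years * DAYS_PER_YEAR
    doy = np.tile(np.arange(1, DAYS_PER_YEAR + 1), config.years)
    year = np.repeat(np.arange(config.start_year,
                               config.start_year + config.years), DAYS_PER_YEAR)
    t = tmean + delta_t + amplitude * np.cos(2 * np.pi * (doy - 201) / DAYS_PER_YEAR)
    precip = np.where(np.arange(n) % precip_every == 0, precip_mm, 0.0)
    return WeatherSeries(year=year, day_of_year=doy, precip=precip,
                         tmin=t - 5.0, tmax=t + 5.0,
                         srad=np.full(n, 18.0), wind=np.full(n, 2.0),
                         rh=np.full(n, 65.0))
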
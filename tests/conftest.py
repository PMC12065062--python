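import dataclasses
import datetime as dt

import pytest

from agroflux.synth import TruthParams
from agroflux.weather import SiteMeta, WeatherDaily


@pytest.fixture(scope="session")
def site() -> SiteMeta:
    return SiteMeta(latitude=40.07, elevation=0.0)


@pytest.fixture
def reference_day() -> WeatherDaily:
    """A fully specified midsummer day used for the step-by-step ET0 oracle."""
    return WeatherDaily(
        date=dt.date(2021, 7, 15),  # DOY 196
        tmax=30.0, tmin=18.0, rhmax=90.0, rhmin=50.0,
        wind=2.0, wind_height=2.0, pressure=101.3,
        sunshine=10.0, precip=0.0,
    )


@pytest.fixture(scope="session")
def one_season_params() -> TruthParams:
    """Single-season campaign: fast enough for per-test generation."""
    return dataclasses.replace(TruthParams(), years=(2021,))


@pytest.fixture(scope="session")
def noiseless_params(one_season_params) -> TruthParams:
    """Single season, perfect sensors, dry season: exact-recovery regime."""
    return dataclasses.replace(
        one_season_params,
        precip_event_prob=0.0,
        sensor_offset_sd=0.0,
        sensor_quant=0.0,
        sensor_noise_sd=0.0,
        initial_tsm_mm=335.0,  # start below field capacity: no drainage at all
    )
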
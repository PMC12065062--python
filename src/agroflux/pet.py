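"""FAO-56 Penman-Monteith daily reference evapotranspiration (ET0).

Implements the full daily chain for the "minimum data" route: saturation and
actual vapour pressure from temperature and relative-humidity extremes,
extraterrestrial radiation from latitude and day of year, solar radiation
from bright-sunshine hours through the Angstrom formula, net radiation with
the FAO cloudiness/humidity longwave correction, soil heat flux taken as
zero at the daily step, and a logarithmic wind-profile adjustment to the
standard 2-m height.

All radiation terms are MJ m-2 day-1, pressures kPa, temperatures deg C
(Kelvin only inside the longwave term), ET0 mm day-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .weather import SiteMeta, WeatherDaily, WeatherError

SOLAR_CONSTANT = 0.0820      # MJ m-2 min-1
STEFAN_BOLTZMANN = 4.903e-9  # MJ K-4 m-2 day-1


class PETError(ValueError):
    """Raised when a day cannot yield a physically valid ET0."""


@dataclass(frozen=True)
class PETDaily:
    """ET0 for one day plus the audit trail of intermediate terms."""

    date: object
    et0: float                 # mm/day
    ra: float                  # extraterrestrial radiation
    daylength: float           # astronomical daylength, h
    rs: float                  # solar radiation (Angstrom)
    rns: float                 # net shortwave
    rnl: float                 # net longwave
    rn: float                  # net radiation
    es: float                  # mean saturation vapour pressure, kPa
    ea: float                  # actual vapour pressure, kPa
    delta: float               # slope of the vapour-pressure curve, kPa/degC
    gamma: float               # psychrometric constant, kPa/degC
    u2: float                  # wind at 2 m, m/s


def saturation_vapor_pressure(temp_c: float) -> float:
    """Tetens-form saturation vapour pressure e0(T), kPa."""
    return 0.6108 * math.exp(17.27 * temp_c / (temp_c + 237.3))


def vapor_pressure_slope(tmean_c: float) -> float:
    """Slope of the saturation curve at the mean temperature, kPa/degC."""
    return 4098.0 * saturation_vapor_pressure(tmean_c) / (tmean_c + 237.3) ** 2


def pressure_from_elevation(elevation_m: float) -> float:
    """FAO-56 standard-atmosphere pressure, kPa."""
    return 101.3 * ((293.0 - 0.0065 * elevation_m) / 293.0) ** 5.26


def psychrometric_constant(pressure_kpa: float) -> float:
    return 0.000665 * pressure_kpa


def wind_at_2m(wind: float, height_m: float) -> float:
    """Logarithmic profile adjustment of wind speed to 2 m."""
    if height_m == 2.0:
        return wind
    return wind * 4.87 / math.log(67.8 * height_m - 5.42)


def extraterrestrial_radiation(latitude_deg: float, doy: int) -> tuple[float, float]:
    """Daily extraterrestrial radiation Ra and astronomical daylength N.

    Returns (Ra MJ m-2 day-1, N hours) for the given latitude and day of
    year.  The sunset-hour-angle argument is clipped for polar day/night.
    """
    phi = math.radians(latitude_deg)
    dr = 1.0 + 0.033 * math.cos(2.0 * math.pi * doy / 365.0)
    decl = 0.409 * math.sin(2.0 * math.pi * doy / 365.0 - 1.39)
    x = -math.tan(phi) * math.tan(decl)
    ws = math.acos(min(1.0, max(-1.0, x)))
    ra = (24.0 * 60.0 / math.pi) * SOLAR_CONSTANT * dr * (
        ws * math.sin(phi) * math.sin(decl) + math.cos(phi) * math.cos(decl) * math.sin(ws)
    )
    daylength = 24.0 / math.pi * ws
    return ra, daylength


def compute_et0(day: WeatherDaily, site: SiteMeta) -> PETDaily:
    """Daily reference evapotranspiration for a validated weather day.

    Raises
    ------
    PETError
        If sunshine exceeds the astronomical daylength or inputs are
        otherwise unusable (humidity and finiteness are already enforced
        by :class:`~agroflux.weather.WeatherDaily`).
    """
    doy = day.date.timetuple().tm_yday
    ra, daylength = extraterrestrial_radiation(site.latitude, doy)
    if day.sunshine > daylength + 1e-9:
        raise PETError(
            f"{day.date}: sunshine {day.sunshine:.2f} h exceeds daylength {daylength:.2f} h"
        )

    tmean = day.tmean
    es = 0.5 * (saturation_vapor_pressure(day.tmax) + saturation_vapor_pressure(day.tmin))
    ea = 0.5 * (
        saturation_vapor_pressure(day.tmin) * day.rhmax / 100.0
        + saturation_vapor_pressure(day.tmax) * day.rhmin / 100.0
    )
    delta = vapor_pressure_slope(tmean)
    pressure = day.pressure if day.pressure is not None else pressure_from_elevation(site.elevation)
    if not math.isfinite(pressure) or pressure <= 0:
        raise PETError(f"{day.date}: invalid pressure {pressure!r}")
    gamma = psychrometric_constant(pressure)

    rel_sunshine = day.sunshine / daylength if daylength > 0 else 0.0
    rs = (site.angstrom_a + site.angstrom_b * rel_sunshine) * ra
    rso = (0.75 + 2e-5 * site.elevation) * ra
    rns = (1.0 - site.albedo) * rs
    if rso > 0:
        cloud_term = 1.35 * min(rs / rso, 1.0) - 0.35
    else:
        cloud_term = 0.0  # polar night: no longwave correction basis
    rnl = (
        STEFAN_BOLTZMANN
        * 0.5 * ((day.tmax + 273.16) ** 4 + (day.tmin + 273.16) ** 4)
        * (0.34 - 0.14 * math.sqrt(ea))
        * cloud_term
    )
    rn = rns - rnl
    u2 = wind_at_2m(day.wind, day.wind_height)

    # G = 0 at the daily time step
    numerator = 0.408 * delta * rn + gamma * (900.0 / (tmean + 273.0)) * u2 * (es - ea)
    denominator = delta + gamma * (1.0 + 0.34 * u2)
    et0 = max(0.0, numerator / denominator)

    return PETDaily(
        date=day.date, et0=et0, ra=ra, daylength=daylength, rs=rs, rns=rns,
        rnl=rnl, rn=rn, es=es, ea=ea, delta=delta, gamma=gamma, u2=u2,
    )


def pet_frame(days: list[WeatherDaily], site: SiteMeta) -> pd.DataFrame:
    """ET0 and audit columns for a list of days."""
    rows = [compute_et0(d, site) for d in days]
    return pd.DataFrame(
        {
            "date": [r.date for r in rows],
            "et0_mm": [r.et0 for r in rows],
            "ra_mj_m2": [r.ra for r in rows],
            "rs_mj_m2": [r.rs for r in rows],
            "rn_mj_m2": [r.rn for r in rows],
            "es_kpa": [r.es for r in rows],
            "ea_kpa": [r.ea for r in rows],
            "delta_kpa_c": [r.delta for r in rows],
            "gamma_kpa_c": [r.gamma for r in rows],
            "u2_ms": [r.u2 for r in rows],
        }
    )
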
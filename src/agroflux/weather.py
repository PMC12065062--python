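"""Daily weather containers and growing-season aggregation.

Weather drives two downstream stages: FAO-56 reference evapotranspiration
(:mod:`agroflux.pet`) and the precipitation-based screening of the soil
water balance (:mod:`agroflux.water_balance`).  Seasonal aggregation follows
the regional reporting convention for the US Midwest: the growing season is
April 1 - September 30, precipitation is summed, and temperature is averaged
month-by-month (each month weighted equally, as climate tables print it).
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field

import pandas as pd

GROWING_SEASON_MONTHS = (4, 5, 6, 7, 8, 9)


class WeatherError(ValueError):
    """Raised when a weather record violates a physical invariant."""


@dataclass(frozen=True)
class WeatherDaily:
    """One day of site meteorology.

    Parameters
    ----------
    date : datetime.date
    tmax, tmin : float
        Daily air temperature extremes, deg C.
    rhmax, rhmin : float
        Relative humidity extremes, percent.
    wind : float
        Mean wind speed, m/s, measured at ``wind_height`` m.
    sunshine : float
        Bright-sunshine duration, hours.
    precip : float
        Precipitation depth, mm/day.
    pressure : float or None
        Atmospheric pressure, kPa.  When None the elevation-based
        FAO-56 approximation is used downstream.
    wind_height : float
        Anemometer height above ground, m (default 2 m).
    """

    date: dt.date
    tmax: float
    tmin: float
    rhmax: float
    rhmin: float
    wind: float
    sunshine: float
    precip: float
    pressure: float | None = None
    wind_height: float = 2.0

    def __post_init__(self) -> None:
        for name in ("tmax", "tmin", "rhmax", "rhmin", "wind", "sunshine", "precip"):
            v = getattr(self, name)
            if v is None or not math.isfinite(v):
                raise WeatherError(f"{self.date}: non-finite {name}={v!r}")
        if self.tmax < self.tmin:
            raise WeatherError(f"{self.date}: tmax {self.tmax} < tmin {self.tmin}")
        if not (0.0 <= self.rhmin <= self.rhmax <= 100.0):
            raise WeatherError(
                f"{self.date}: humidity out of range (rhmin={self.rhmin}, rhmax={self.rhmax})"
            )
        if self.wind < 0:
            raise WeatherError(f"{self.date}: negative wind {self.wind}")
        if self.sunshine < 0:
            raise WeatherError(f"{self.date}: negative sunshine {self.sunshine}")
        if self.precip < 0:
            raise WeatherError(f"{self.date}: negative precip {self.precip}")
        if self.wind_height <= 0:
            raise WeatherError(f"{self.date}: wind height must be positive")

    @property
    def tmean(self) -> float:
        return 0.5 * (self.tmax + self.tmin)


@dataclass(frozen=True)
class SiteMeta:
    """Static site constants used by the FAO-56 chain.

    Albedo and the Angstrom coefficients default to the FAO-56 reference
    values for a grass surface and average atmospheric turbidity.
    """

    latitude: float
    elevation: float = 0.0
    albedo: float = 0.23
    angstrom_a: float = 0.25
    angstrom_b: float = 0.50

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise WeatherError(f"latitude {self.latitude} out of [-90, 90]")
        if not 0.0 < self.albedo < 1.0:
            raise WeatherError(f"albedo {self.albedo} out of (0, 1)")


@dataclass(frozen=True)
class SeasonWindow:
    """A labelled inclusive date window (e.g. a growing season)."""

    label: str
    start: dt.date
    end: dt.date

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise WeatherError(f"window {self.label!r}: start {self.start} > end {self.end}")

    def contains(self, day: dt.date) -> bool:
        return self.start <= day <= self.end

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1


def growing_season(year: int, label: str | None = None) -> SeasonWindow:
    """April 1 - September 30 of ``year`` (the reporting convention)."""
    return SeasonWindow(label or f"GS{year}", dt.date(year, 4, 1), dt.date(year, 9, 30))


def weather_frame(days: list[WeatherDaily]) -> pd.DataFrame:
    """Tabulate validated daily records."""
    return pd.DataFrame(
        {
            "date": [d.date for d in days],
            "tmax_c": [d.tmax for d in days],
            "tmin_c": [d.tmin for d in days],
            "rhmax_pct": [d.rhmax for d in days],
            "rhmin_pct": [d.rhmin for d in days],
            "wind_ms": [d.wind for d in days],
            "wind_height_m": [d.wind_height for d in days],
            "pressure_kpa": [d.pressure for d in days],
            "sunshine_h": [d.sunshine for d in days],
            "precip_mm": [d.precip for d in days],
        }
    )


def monthly_climate(daily: pd.DataFrame) -> pd.DataFrame:
    """Collapse a daily frame (date, tmax_c/tmin_c or tmean_c, precip_mm) to
    monthly mean temperature and total precipitation."""
    df = daily.copy()
    df["date"] = pd.to_datetime(df["date"])
    if "tmean_c" not in df.columns:
        df["tmean_c"] = 0.5 * (df["tmax_c"] + df["tmin_c"])
    grp = df.groupby([df["date"].dt.year.rename("year"), df["date"].dt.month.rename("month")])
    out = grp.agg(tmean_c=("tmean_c", "mean"), precip_mm=("precip_mm", "sum")).reset_index()
    return out


def aggregate_season(
    monthly: pd.DataFrame,
    year: int,
    months: tuple[int, ...] = GROWING_SEASON_MONTHS,
) -> dict[str, float]:
    """Seasonal climate summary from a monthly table.

    ``monthly`` must carry columns year, month, tmean_c, precip_mm.
    Precipitation is summed and temperature averaged with equal monthly
    weight.  Rounding is left to the caller (report at one decimal).

    Raises
    ------
    WeatherError
        If any requested month is missing from the table.
    """
    sel = monthly[(monthly["year"] == year) & (monthly["month"].isin(months))]
    missing = sorted(set(months) - set(sel["month"]))
    if missing:
        raise WeatherError(f"year {year}: months {missing} absent from climate table")
    return {
        "precip_mm": float(sel["precip_mm"].sum()),
        "tmean_c": float(sel["tmean_c"].mean()),
        "n_months": int(len(sel)),
    }


def aggregate_annual(monthly: pd.DataFrame, year: int) -> dict[str, float]:
    """Calendar-year totals/means (all 12 months required)."""
    return aggregate_season(monthly, year, months=tuple(range(1, 13)))
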
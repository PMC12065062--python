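"""Synthetic field campaign with known ground truth.

Generates every input the pipeline consumes — daily weather, profile
soil-moisture sensor logs, static-chamber concentration ramps, harvest
records and pore-water nitrate samples — from a single parameter set and
seed, together with a truth log, so each stage's recovery can be checked
end to end without any field data.

What the generators emulate
---------------------------
* Weather: a humid-continental Midwest season — sinusoidal temperature
  normals with synoptic noise, Bernoulli-gamma precipitation, sunshine and
  humidity anti-correlated with rain.  The default parameters give a
  growing-season (Apr-Sep) mean temperature near 19 C and expected
  growing-season precipitation near 600 mm; the ``drought`` preset cuts
  precipitation ~27%.
* Soil moisture: an hourly single-bucket profile.  Storage gains effective
  precipitation, loses the day's true ET distributed over daylight hours
  (nothing between 0000 and 0400 h), and drains by first-order relaxation
  toward field capacity whenever storage exceeds it.  The true daily ET is
  a crop-coefficient curve applied to the FAO-56 ET0 of the generated
  weather, as in a real canopy; the realized values are recorded in the
  truth log.  Bucket storage is disaggregated to sensor-depth VWC with
  fixed weights chosen so the pipeline's trapezoidal re-integration
  reproduces the bucket exactly, then Gaussian sensor noise is added.
* Chambers: linear headspace ramps whose slopes invert the ideal-gas
  conversion at the configured true flux, plus Gaussian analyzer noise.
* Leachate: lognormal samples around crop-depth means, with the perennial
  crop's mean declining year on year relative to the reference crop.

The generators are pure functions of (params, seed): the same inputs give
identical output, and each generator draws from its own seeded stream so
they can be called in any order.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import pet as petmod
from .chambers import ELEMENT_MASS, R_GAS, SECONDS_PER_DAY, ChamberGeometry
from .weather import SiteMeta

# TSM (mm) -> VWC weights at 30/60/90 cm.  Trapezoidal re-integration of
# theta_i = w_i * TSM gives 450*w1 + 300*w2 + 150*w3 = 1 (slightly slower
# dynamics with depth), so the pipeline recovers the bucket exactly.
_DEPTHS_CM = (30.0, 60.0, 90.0)
_SHAPE = (1.0, 0.95, 0.90)
_WEIGHTS = tuple(s / (450 * _SHAPE[0] + 300 * _SHAPE[1] + 150 * _SHAPE[2]) for s in _SHAPE)


class SynthError(ValueError):
    pass


@dataclass(frozen=True)
class TruthParams:
    """Ground-truth configuration for one synthetic campaign."""

    years: tuple[int, ...] = (2020, 2021, 2022)
    crops: tuple[str, ...] = ("corn", "switchgrass")
    n_blocks: int = 3
    site: SiteMeta = field(default_factory=lambda: SiteMeta(latitude=40.07, elevation=220.0))

    # season geometry (month, day)
    weather_start: tuple[int, int] = (3, 1)
    season_start: tuple[int, int] = (4, 1)
    season_end: tuple[int, int] = (9, 30)
    emergence: tuple[int, int] = (5, 1)

    # weather process
    tmean_annual_c: float = 11.0
    tamp_c: float = 13.8           # seasonal amplitude; peak at doy 196
    tnoise_sd_c: float = 2.0
    diurnal_range_c: float = 10.0
    precip_event_prob: float = 0.30
    precip_mean_depth_mm: float = 11.0
    precip_scale: float = 1.0      # drought preset: 0.73

    # bucket model
    field_capacity_mm: float = 340.0
    initial_tsm_mm: float = 350.0
    drainage_rate_per_h: float = 0.15
    # Sensor error model: a static per-sensor calibration offset (dominant in
    # practice; cancels in the storage differences the method uses), output
    # quantization at the instrument resolution, and a small Gaussian read
    # noise.  Modelling the read noise much larger than real loggers show
    # makes the 24x-amplified nightly-drainage estimate rectify noise into a
    # spurious water loss — a sensitivity of the method itself, not of this
    # implementation.
    sensor_offset_sd: float = 0.01          # cm3/cm3, per-sensor calibration bias
    sensor_quant: float = 0.001             # cm3/cm3, output resolution
    sensor_noise_sd: float = 5e-5           # cm3/cm3, sub-resolution electronic noise
    kc_pre_emergence: float = 0.25          # bare-soil evaporation
    kc_peak: dict = field(default_factory=lambda: {"corn": 1.05, "switchgrass": 1.10})

    # chamber process
    chamber_noise_sd_ppm: float = 1.0
    chambers_per_plot: int = 3
    sampling_interval_days: int = 7
    co2_peak_g_m2_d: dict = field(
        default_factory=lambda: {"corn": 5.0, "switchgrass": 7.0}
    )
    co2_establishment_factor: float = 0.65   # first-year perennial: no mature roots
    n2o_base_mg_m2_d: dict = field(
        default_factory=lambda: {"corn": 1.0, "switchgrass": 0.5}
    )
    n2o_pulse_mg_m2_d: dict = field(
        default_factory=lambda: {"corn": 8.0, "switchgrass": 2.0}
    )

    # biomass truth (kg/ha AGB per crop per season index)
    agb_kg_ha: dict = field(
        default_factory=lambda: {
            "corn": (11_700.0, 11_000.0, 10_100.0),
            "switchgrass": (3_800.0, 16_700.0, 12_400.0),
        }
    )
    corn_grain_moisture_pct: float = 18.0
    switchgrass_moisture_pct: float = 55.0
    agb_cv: float = 0.05

    # leachate decline model
    no3_corn_mean_mg_l: dict = field(default_factory=lambda: {30: 14.0, 90: 10.0})
    no3_reduction_pct_by_season: tuple[float, ...] = (20.0, 60.0, 80.0)
    no3_lognormal_sd: float = 0.25
    leachate_samples_per_month: int = 2

    @property
    def plots(self) -> list[tuple[str, str]]:
        """(plot_id, crop) pairs: crops x blocks."""
        return [
            (f"{crop[0].upper()}{b + 1}", crop)
            for crop in self.crops
            for b in range(self.n_blocks)
        ]

    @property
    def expected_season_precip_mm(self) -> float:
        """Expected Apr-Sep precipitation under the configured process."""
        n_days = 183
        return n_days * self.precip_event_prob * self.precip_mean_depth_mm * self.precip_scale

    def dates(self, year: int) -> dict[str, dt.date]:
        return {
            "weather_start": dt.date(year, *self.weather_start),
            "season_start": dt.date(year, *self.season_start),
            "season_end": dt.date(year, *self.season_end),
            "emergence": dt.date(year, *self.emergence),
        }


def drought_params(**overrides) -> TruthParams:
    """Preset with growing-season precipitation ~27% below normal."""
    return TruthParams(precip_scale=0.73, **overrides)


def _rng(seed: int, stream: int, year: int = 0) -> np.random.Generator:
    return np.random.default_rng([seed, stream, year])


# ------------------------------------------------------------------- weather

def gen_weather(params: TruthParams, year: int, seed: int) -> pd.DataFrame:
    """Daily weather from weather_start through season_end of ``year``."""
    d = params.dates(year)
    if d["weather_start"] > d["season_end"]:
        raise SynthError("degenerate weather window")
    rng = _rng(seed, 1, year)
    days = pd.date_range(d["weather_start"], d["season_end"], freq="D")
    doy = np.array([t.dayofyear for t in days], dtype=float)

    tmean = (
        params.tmean_annual_c
        + params.tamp_c * np.cos(2 * np.pi * (doy - 196.0) / 365.0)
        + rng.normal(0.0, params.tnoise_sd_c, len(days))
    )
    half_range = params.diurnal_range_c / 2.0
    tmax = tmean + half_range
    tmin = tmean - half_range

    wet = rng.random(len(days)) < params.precip_event_prob
    depth = rng.gamma(shape=1.5, scale=params.precip_mean_depth_mm / 1.5, size=len(days))
    precip = np.where(wet, depth * params.precip_scale, 0.0)

    daylength = np.array(
        [petmod.extraterrestrial_radiation(params.site.latitude, int(j))[1] for j in doy]
    )
    sun_frac = np.where(
        wet, rng.uniform(0.0, 0.35, len(days)), rng.uniform(0.45, 0.95, len(days))
    )
    sunshine = sun_frac * daylength

    rhmax = np.clip(np.where(wet, rng.uniform(90, 100, len(days)),
                             rng.uniform(75, 95, len(days))), 0, 100)
    rhmin = np.clip(np.where(wet, rng.uniform(60, 80, len(days)),
                             rng.uniform(35, 60, len(days))), 0, 100)
    rhmin = np.minimum(rhmin, rhmax)
    wind = rng.lognormal(mean=math.log(2.2), sigma=0.4, size=len(days))
    pressure = petmod.pressure_from_elevation(params.site.elevation)

    return pd.DataFrame(
        {
            "date": days.date,
            "tmax_c": tmax,
            "tmin_c": tmin,
            "rhmax_pct": rhmax,
            "rhmin_pct": rhmin,
            "wind_ms": wind,
            "wind_height_m": 2.0,
            "pressure_kpa": pressure,
            "sunshine_h": sunshine,
            "precip_mm": precip,
        }
    )


def _true_et_schedule(
    params: TruthParams, weather: pd.DataFrame, crop: str, year: int
) -> pd.DataFrame:
    """Daily true ET = kc(day) x FAO-56 ET0 of the generated weather.

    kc ramps from a bare-soil value before emergence to the crop peak at
    mid-season and eases off toward senescence.
    """
    from .weather import WeatherDaily

    d = params.dates(year)
    peak = params.kc_peak[crop]
    rows = []
    for _, r in weather.iterrows():
        day = WeatherDaily(
            date=r["date"], tmax=r["tmax_c"], tmin=r["tmin_c"],
            rhmax=r["rhmax_pct"], rhmin=r["rhmin_pct"], wind=r["wind_ms"],
            sunshine=min(r["sunshine_h"],
                         petmod.extraterrestrial_radiation(
                             params.site.latitude, r["date"].timetuple().tm_yday)[1]),
            precip=r["precip_mm"], pressure=r["pressure_kpa"],
            wind_height=r["wind_height_m"],
        )
        et0 = petmod.compute_et0(day, params.site).et0
        if r["date"] < d["emergence"]:
            kc = params.kc_pre_emergence
        else:
            frac = (r["date"] - d["emergence"]).days / max(
                1, (d["season_end"] - d["emergence"]).days
            )
            # rise to peak by mid-season, mild late-season decline
            kc = params.kc_pre_emergence + (peak - params.kc_pre_emergence) * min(
                1.0, frac / 0.5
            )
            if frac > 0.8:
                kc *= 1.0 - 0.5 * (frac - 0.8) / 0.2
        rows.append({"date": r["date"], "et0_mm": et0, "true_et_mm": kc * et0})
    return pd.DataFrame(rows)


# -------------------------------------------------------------- soil moisture

def _diurnal_weights() -> np.ndarray:
    """Hourly ET weights: zero from 0000 to 0400 h, sine hump in daytime."""
    w = np.zeros(24)
    for h in range(5, 21):
        w[h] = math.sin(math.pi * (h - 5) / 15.0)
    return w / w.sum()


def gen_soil_moisture(
    params: TruthParams, weather: pd.DataFrame, year: int, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hourly VWC sensor logs plus the daily truth log, all plots, one year.

    Returns (vwc, truth).  ``vwc``: timestamp, plot_id, depth_cm, vwc.
    ``truth``: plot_id, date, true_et_mm, et0_mm, precip_mm, drainage_mm,
    tsm_0000_true.
    """
    if params.field_capacity_mm > 900.0:
        raise SynthError("field capacity above profile saturation")
    d = params.dates(year)
    start = d["season_start"]
    end = d["season_end"]
    wx = weather.set_index("date")
    weights = _diurnal_weights()

    vwc_parts, truth_rows = [], []
    for plot_id, crop in params.plots:
        plot_tag = int.from_bytes(plot_id.encode(), "little") % 9973  # stable across runs
        rng = _rng(seed, 2, year * 10_000 + plot_tag)
        schedule = _true_et_schedule(params, weather, crop, year).set_index("date")
        tsm = params.initial_tsm_mm
        n_days = (end - start).days + 1
        times, tsms = [], []
        for k in range(n_days + 1):
            day = start + dt.timedelta(days=k)
            last = k == n_days  # final midnight only
            day_precip = 0.0 if last else float(wx.loc[day, "precip_mm"])
            precip_hour = int(rng.integers(0, 24))
            demand_et = 0.0 if last else float(schedule.loc[day, "true_et_mm"])
            drained = 0.0
            realized_et = 0.0
            tsm_0000 = tsm
            for hour in range(24):
                times.append(dt.datetime.combine(day, dt.time(hour)))
                tsms.append(tsm)
                if last:
                    break
                if day_precip > 0 and hour == precip_hour:
                    tsm += day_precip
                # extraction is supply-limited: a dry bucket cannot transpire
                step = min(demand_et * weights[hour], tsm)
                tsm -= step
                realized_et += step
                if tsm > params.field_capacity_mm:
                    q = params.drainage_rate_per_h * (tsm - params.field_capacity_mm)
                    tsm -= q
                    drained += q
            if not last:
                truth_rows.append(
                    {
                        "plot_id": plot_id,
                        "date": day,
                        "true_et_mm": realized_et,
                        "et0_mm": float(schedule.loc[day, "et0_mm"]),
                        "precip_mm": day_precip,
                        "drainage_mm": drained,
                        "tsm_0000_true": tsm_0000,
                    }
                )
        tsm_arr = np.asarray(tsms)
        for depth, w in zip(_DEPTHS_CM, _WEIGHTS):
            offset = rng.normal(0.0, params.sensor_offset_sd)
            theta = (
                w * tsm_arr + offset
                + rng.normal(0.0, params.sensor_noise_sd, len(tsm_arr))
            )
            if params.sensor_quant > 0:
                theta = np.round(theta / params.sensor_quant) * params.sensor_quant
            vwc_parts.append(
                pd.DataFrame(
                    {
                        "timestamp": times,
                        "plot_id": plot_id,
                        "depth_cm": depth,
                        "vwc": np.clip(theta, 0.0, 1.0),
                    }
                )
            )
    return pd.concat(vwc_parts, ignore_index=True), pd.DataFrame(truth_rows)


# ------------------------------------------------------------------- chambers

def _true_gas_flux(params: TruthParams, crop: str, season_index: int, date: dt.date,
                   gas: str, year: int) -> float:
    """True element-mass flux g m-2 day-1 for a plot-date."""
    doy = date.timetuple().tm_yday
    if gas == "CO2":
        peak = params.co2_peak_g_m2_d[crop]
        if crop == "switchgrass" and season_index == 0:
            peak *= params.co2_establishment_factor
        return peak * math.exp(-(((doy - 200.0) / 60.0) ** 2))
    # N2O: baseline plus an early-summer fertilization/rain pulse (mg -> g)
    base = params.n2o_base_mg_m2_d[crop]
    pulse = params.n2o_pulse_mg_m2_d[crop] * math.exp(-(((doy - 165.0) / 12.0) ** 2))
    return (base + pulse) / 1000.0


def mass_flux_to_slope(
    mass_flux_g_m2_d: float, geom: ChamberGeometry, gas: str,
    air_temp_k: float, pressure_pa: float,
) -> float:
    """Invert the ideal-gas chain: element-mass flux -> ramp slope (ppm/s)."""
    if air_temp_k <= 0 or pressure_pa <= 0:
        raise SynthError("temperature and pressure must be positive")
    molar = mass_flux_g_m2_d / (ELEMENT_MASS[gas] * SECONDS_PER_DAY)
    headspace_mol = pressure_pa * geom.volume / (R_GAS * air_temp_k)
    return molar * geom.area / headspace_mol * 1e6


def gen_chamber_series(
    params: TruthParams,
    year: int,
    seed: int,
    geometry: ChamberGeometry | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Concentration ramps for all plots and sampling dates of one season.

    Returns (chamber, truth).  ``chamber``: plot_id, chamber_id, date, gas,
    elapsed_s, ppm, air_temp_c, pressure_kpa (one row per 20-s point).
    ``truth``: plot_id, crop, date, gas, true_flux_g_m2_d.
    """
    geom = geometry or ChamberGeometry()
    d = params.dates(year)
    season_index = params.years.index(year) if year in params.years else 0
    rng = _rng(seed, 3, year)
    elapsed = np.arange(16) * 20.0
    sampling = []
    day = d["emergence"]
    while day <= d["season_end"]:
        sampling.append(day)
        day += dt.timedelta(days=params.sampling_interval_days)

    base_ppm = {"CO2": 420.0, "N2O": 0.333}
    chamber_rows, truth_rows = [], []
    for plot_id, crop in params.plots:
        for date in sampling:
            air_t_k = 273.15 + 20.0 + 8.0 * math.sin(
                2 * math.pi * (date.timetuple().tm_yday - 105) / 365.0
            )
            p_pa = 101_325.0
            for gas in ("CO2", "N2O"):
                true_flux = _true_gas_flux(params, crop, season_index, date, gas, year)
                truth_rows.append(
                    {
                        "plot_id": plot_id, "crop": crop, "date": date, "gas": gas,
                        "true_flux_g_m2_d": true_flux,
                    }
                )
                slope = mass_flux_to_slope(true_flux, geom, gas, air_t_k, p_pa)
                for c in range(params.chambers_per_plot):
                    noise_sd = params.chamber_noise_sd_ppm * (1.0 if gas == "CO2" else 0.005)
                    ppm = base_ppm[gas] + slope * elapsed + rng.normal(0, noise_sd, 16)
                    ppm = np.maximum(ppm, 1e-6)
                    for t, conc in zip(elapsed, ppm):
                        chamber_rows.append(
                            {
                                "plot_id": plot_id,
                                "chamber_id": f"{plot_id}-ch{c + 1}",
                                "date": date,
                                "gas": gas,
                                "elapsed_s": t,
                                "ppm": conc,
                                "air_temp_c": air_t_k - 273.15,
                                "pressure_kpa": p_pa / 1000.0,
                            }
                        )
    return pd.DataFrame(chamber_rows), pd.DataFrame(truth_rows)


# -------------------------------------------------------------------- biomass

def gen_biomass(params: TruthParams, year: int, seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Harvest records per plot plus the AGB truth.

    Corn: machine-harvested grain at field moisture over the plot area;
    the pipeline recovers AGB through the harvest index.  The perennial:
    fresh quadrat bundles at cutting moisture.
    """
    rng = _rng(seed, 4, year)
    season_index = params.years.index(year) if year in params.years else 0
    rows, truth_rows = [], []
    for plot_id, crop in params.plots:
        agb_true = params.agb_kg_ha[crop][min(season_index, len(params.agb_kg_ha[crop]) - 1)]
        agb_plot = agb_true * (1.0 + rng.normal(0.0, params.agb_cv))
        truth_rows.append({"plot_id": plot_id, "crop": crop, "year": year,
                           "true_agb_kg_ha": agb_plot})
        if crop == "corn":
            area = 2000.0
            dry_grain_kg = agb_plot * 0.545 * area / 10_000.0
            fresh = dry_grain_kg / (1.0 - params.corn_grain_moisture_pct / 100.0)
            rows.append(
                {
                    "plot_id": plot_id, "crop": crop, "year": year, "kind": "grain",
                    "fresh_mass_kg": fresh,
                    "moisture_pct": params.corn_grain_moisture_pct,
                    "area_m2": area,
                }
            )
        else:
            for q in range(3):
                area = 1.0
                dry_kg = agb_plot * area / 10_000.0
                fresh = dry_kg / (1.0 - params.switchgrass_moisture_pct / 100.0)
                rows.append(
                    {
                        "plot_id": plot_id, "crop": crop, "year": year,
                        "kind": f"quadrat{q + 1}",
                        "fresh_mass_kg": fresh,
                        "moisture_pct": params.switchgrass_moisture_pct,
                        "area_m2": area,
                    }
                )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


# -------------------------------------------------------------------- leachate

def gen_leachate_series(
    params: TruthParams, year: int, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Monthly pore-water NO3-N samples per plot and depth, one season.

    The reference crop's means are stationary; the perennial's means are
    reduced by the configured percent for that stand age.
    """
    season_index = params.years.index(year) if year in params.years else 0
    reduction = params.no3_reduction_pct_by_season[
        min(season_index, len(params.no3_reduction_pct_by_season) - 1)
    ]
    if not 0.0 <= reduction < 100.0:
        raise SynthError(f"reduction {reduction}% out of [0, 100)")
    rng = _rng(seed, 5, year)
    sigma = params.no3_lognormal_sd
    rows, truth_rows = [], []
    for depth, corn_mean in params.no3_corn_mean_mg_l.items():
        means = {"corn": corn_mean, "switchgrass": corn_mean * (1.0 - reduction / 100.0)}
        for crop, mean in means.items():
            truth_rows.append(
                {"year": year, "crop": crop, "depth_cm": depth,
                 "true_mean_mg_l": mean, "true_reduction_pct": reduction}
            )
        for plot_id, crop in params.plots:
            mean = means[crop]
            mu = math.log(mean) - sigma**2 / 2.0
            for month in (5, 6, 7, 8, 9):
                for s in range(params.leachate_samples_per_month):
                    rows.append(
                        {
                            "date": dt.date(year, month, 10 + 5 * s),
                            "plot_id": plot_id,
                            "crop": crop,
                            "depth_cm": depth,
                            "no3n_mg_l": float(rng.lognormal(mu, sigma)),
                        }
                    )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


# ------------------------------------------------------------------- scenario

def write_scenario(
    out_dir: str | Path,
    seed: int,
    scenario: str = "default",
    params: TruthParams | None = None,
) -> dict[str, Path]:
    """Write the full multi-season campaign (CSV inputs + truth.json)."""
    if params is None:
        if scenario == "default":
            params = TruthParams()
        elif scenario == "drought":
            params = drought_params()
        else:
            raise SynthError(f"unknown scenario {scenario!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    weather_parts, vwc_parts, chamber_parts, biomass_parts, leachate_parts = [], [], [], [], []
    truth: dict = {
        "seed": seed,
        "scenario": scenario,
        "field_capacity_mm": params.field_capacity_mm,
        "expected_season_precip_mm": params.expected_season_precip_mm,
        "emergence": {},
        "soil_moisture": [],
        "chambers": [],
        "biomass": [],
        "leachate": [],
    }
    for year in params.years:
        d = params.dates(year)
        truth["emergence"][str(year)] = d["emergence"].isoformat()
        wx = gen_weather(params, year, seed)
        weather_parts.append(wx)
        vwc, sm_truth = gen_soil_moisture(params, wx, year, seed)
        vwc_parts.append(vwc)
        truth["soil_moisture"].extend(
            {**r, "date": r["date"].isoformat(), "year": year}
            for r in sm_truth.to_dict("records")
        )
        chamber, ch_truth = gen_chamber_series(params, year, seed)
        chamber_parts.append(chamber)
        truth["chambers"].extend(
            {**r, "date": r["date"].isoformat(), "year": year}
            for r in ch_truth.to_dict("records")
        )
        bm, bm_truth = gen_biomass(params, year, seed)
        biomass_parts.append(bm)
        truth["biomass"].extend(bm_truth.to_dict("records"))
        lc, lc_truth = gen_leachate_series(params, year, seed)
        leachate_parts.append(lc)
        truth["leachate"].extend(lc_truth.to_dict("records"))

    paths = {}
    for name, frame in (
        ("weather", pd.concat(weather_parts, ignore_index=True)),
        ("vwc", pd.concat(vwc_parts, ignore_index=True)),
        ("chamber", pd.concat(chamber_parts, ignore_index=True)),
        ("biomass", pd.concat(biomass_parts, ignore_index=True)),
        ("leachate", pd.concat(leachate_parts, ignore_index=True)),
    ):
        p = out / f"{name}.csv"
        frame.to_csv(p, index=False)
        paths[name] = p
    tp = out / "truth.json"
    tp.write_text(json.dumps(truth, indent=1))
    paths["truth"] = tp
    return paths
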
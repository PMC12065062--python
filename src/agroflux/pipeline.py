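"""End-to-end orchestration: weather/PET -> chamber fluxes -> water-balance
ET -> biomass/WUE -> leachate summaries -> season summary tables.

The pipeline consumes a directory of CSV inputs (the shapes written by
:func:`agroflux.synth.write_scenario` or assembled from field exports),
runs every stage for every plot-season, and writes CSV outputs plus a run
log.  When a ``truth.json`` ground-truth log is present (synthetic runs) a
recovery report comparing estimates against truth is added.  Group
statistics in summaries are descriptive (mean +/- SE); no inferential
modelling is performed here.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chambers as ch
from . import water_balance as wb
from .biomass import corn_agb_from_grain, dry_matter_yield, HarvestRecord
from .leachate import crop_reduction_by_year, summarize_no3
from .pet import compute_et0
from .weather import SiteMeta, WeatherDaily


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Everything a run needs, loadable from a flat key: value file.

    ``emergence_month``/``emergence_day`` set the crop-emergence date in
    every season (per-year overrides via ``emergence_dates``); the ET and
    cumulation window runs from emergence to ``season_end_month/day``.
    N-rate entries are descriptive run metadata only.
    """

    input_dir: str = "."
    out_dir: str = "out"
    latitude: float = 40.07
    elevation_m: float = 220.0
    emergence_month: int = 5
    emergence_day: int = 1
    season_end_month: int = 9
    season_end_day: int = 30
    eq1_literal: bool = False
    fc_override_mm: float | None = None
    r2_threshold: float = 0.7
    precip_lag_days: int = 3
    corn_n_rate_kg_ha: float = 202.0
    perennial_n_rate_kg_ha: float = 56.0
    seed: int = 0
    emergence_dates: dict = field(default_factory=dict)  # {year: "YYYY-MM-DD"}

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def emergence(self, year: int) -> dt.date:
        if year in self.emergence_dates:
            return dt.date.fromisoformat(str(self.emergence_dates[year]))
        if str(year) in self.emergence_dates:
            return dt.date.fromisoformat(str(self.emergence_dates[str(year)]))
        return dt.date(year, self.emergence_month, self.emergence_day)

    def season_end(self, year: int) -> dt.date:
        return dt.date(year, self.season_end_month, self.season_end_day)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _require(path: Path) -> Path:
    if not path.exists():
        raise PipelineError(f"required input file missing: {path}")
    return path


def _weather_days(weather: pd.DataFrame) -> list[WeatherDaily]:
    days = []
    for _, r in weather.iterrows():
        days.append(
            WeatherDaily(
                date=pd.Timestamp(r["date"]).date(),
                tmax=float(r["tmax_c"]), tmin=float(r["tmin_c"]),
                rhmax=float(r["rhmax_pct"]), rhmin=float(r["rhmin_pct"]),
                wind=float(r["wind_ms"]),
                wind_height=float(r.get("wind_height_m", 2.0)),
                pressure=None if pd.isna(r.get("pressure_kpa")) else float(r["pressure_kpa"]),
                sunshine=float(r["sunshine_h"]), precip=float(r["precip_mm"]),
            )
        )
    return days


def _stage_pet(weather: pd.DataFrame, site: SiteMeta) -> pd.DataFrame:
    rows = []
    for day in _weather_days(weather):
        p = compute_et0(day, site)
        rows.append({"date": pd.Timestamp(p.date), "et0_mm": p.et0, "rn_mj_m2": p.rn,
                     "es_kpa": p.es, "ea_kpa": p.ea, "u2_ms": p.u2})
    return pd.DataFrame(rows)


def _stage_fluxes(chamber: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    estimates = []
    geom = ch.ChamberGeometry()
    for (plot, cid, date, gas), grp in chamber.groupby(
        ["plot_id", "chamber_id", "date", "gas"], sort=True
    ):
        grp = grp.sort_values("elapsed_s")
        series = ch.ConcentrationSeries(
            plot_id=plot, chamber_id=cid, date=pd.Timestamp(date).date(), gas=gas,
            elapsed_s=grp["elapsed_s"].to_numpy(),
            ppm=grp["ppm"].to_numpy(),
            air_temp_k=float(grp["air_temp_c"].iloc[0]) + 273.15,
            pressure_pa=float(grp["pressure_kpa"].iloc[0]) * 1000.0,
        )
        estimates.append(ch.estimate_flux(series, geom, r2_threshold=config.r2_threshold))
    return ch.flux_frame(estimates)


def _stage_biomass(biomass: pd.DataFrame) -> pd.DataFrame:
    """Per plot-year AGB (kg/ha): grain records via the harvest index,
    direct-biomass records (e.g. quadrats) averaged."""
    rows = []
    for (plot, crop, year), grp in biomass.groupby(["plot_id", "crop", "year"], sort=True):
        vals = []
        for _, r in grp.iterrows():
            rec = HarvestRecord(
                plot_id=plot, crop=crop, fresh_mass_kg=float(r["fresh_mass_kg"]),
                moisture_pct=float(r["moisture_pct"]), area_m2=float(r["area_m2"]),
            )
            dry = dry_matter_yield(rec)
            vals.append(corn_agb_from_grain(dry) if str(r["kind"]) == "grain" else dry)
        rows.append({"plot_id": plot, "crop": crop, "year": int(year),
                     "agb_kg_ha": float(np.mean(vals))})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Execute all stages; write outputs under ``config.out_dir``.

    Returns the output tables keyed by name.  Any stage failure removes
    partial outputs and raises :class:`PipelineError` naming the stage.
    """
    in_dir = Path(config.input_dir)
    out_dir = Path(config.out_dir)
    site = SiteMeta(latitude=config.latitude, elevation=config.elevation_m)

    weather = pd.read_csv(_require(in_dir / "weather.csv"), parse_dates=["date"])
    vwc = pd.read_csv(_require(in_dir / "vwc.csv"), parse_dates=["timestamp"])
    chamber = pd.read_csv(_require(in_dir / "chamber.csv"), parse_dates=["date"])
    biomass = pd.read_csv(_require(in_dir / "biomass.csv"))
    leachate = pd.read_csv(_require(in_dir / "leachate.csv"), parse_dates=["date"])
    truth_path = in_dir / "truth.json"
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else None

    outputs: dict[str, pd.DataFrame] = {}
    stage = "setup"
    try:
        stage = "weather_pet"
        pet = _stage_pet(weather, site)
        outputs["pet"] = pet

        stage = "chamber_flux"
        fluxes = _stage_fluxes(chamber, config)
        outputs["fluxes"] = fluxes
        obs = fluxes.rename(columns={"mass_flux_g_m2_d": "mass_flux_g_m2_d"})[
            ["plot_id", "gas", "date", "mass_flux_g_m2_d"]
        ].copy()
        obs["year"] = pd.to_datetime(obs["date"]).dt.year
        daily_parts, cum_rows = [], []
        for year, grp in obs.groupby("year"):
            daily = ch.interpolate_daily_flux(grp.drop(columns="year"))
            daily["year"] = year
            daily_parts.append(daily)
            for e in ch.cumulate_emissions(
                daily, config.emergence(int(year)), config.season_end(int(year)),
                label=f"GS{year}",
            ):
                cum_rows.append(dataclasses.asdict(e) | {"year": int(year)})
        outputs["daily_flux"] = pd.concat(daily_parts, ignore_index=True)
        outputs["cumulative"] = pd.DataFrame(cum_rows)

        stage = "water_balance"
        tsm = wb.tsm_series(vwc)
        tsm["year"] = tsm["timestamp"].dt.year
        agb = _stage_biomass(biomass)
        crop_of = dict(zip(agb["plot_id"], agb["crop"]))
        et_parts, season_rows = [], []
        for year, tsm_y in tsm.groupby("year"):
            year = int(year)
            emergence = config.emergence(year)
            window = (emergence, config.season_end(year))
            precip = weather[pd.to_datetime(weather["date"]).dt.year == year][
                ["date", "precip_mm"]
            ]
            pet_y = pet[pet["date"].dt.year == year]
            if config.fc_override_mm is not None:
                fc = wb.FieldCapacity(
                    fc_mm=config.fc_override_mm, window_start=emergence,
                    window_end=emergence, n_readings=0, level="override",
                )
            else:
                fc = wb.estimate_field_capacity(tsm_y, emergence)
            for plot in sorted(tsm_y["plot_id"].unique()):
                filled, _ = wb.plot_daily_et(
                    tsm_y, precip, pet_y, plot, emergence, *window,
                    fc=fc, eq1_literal=config.eq1_literal,
                    precip_lag_days=config.precip_lag_days,
                )
                filled["year"] = year
                et_parts.append(filled)
                agb_row = agb[(agb["plot_id"] == plot) & (agb["year"] == year)]
                agb_val = float(agb_row["agb_kg_ha"].iloc[0]) if len(agb_row) else 0.0
                sw = wb.season_water_summary(
                    filled, agb_val, *window, plot_id=plot, season=f"GS{year}"
                )
                season_rows.append(dataclasses.asdict(sw) | {"year": year,
                                                             "crop": crop_of.get(plot, "")})
        outputs["daily_et"] = pd.concat(et_parts, ignore_index=True)
        outputs["season_water"] = pd.DataFrame(season_rows)
        outputs["biomass_summary"] = agb

        stage = "leachate"
        outputs["no3_summary"] = summarize_no3(leachate)
        try:
            outputs["no3_reduction"] = crop_reduction_by_year(
                leachate, "corn", "switchgrass"
            )
        except Exception:
            pass  # single-crop campaigns have no between-crop contrast

        stage = "season_summary"
        outputs["season_summary"] = _season_summary(outputs)

        if truth is not None:
            stage = "truth_recovery"
            outputs["recovery"] = _recovery_report(outputs, truth)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    try:
        for name, frame in outputs.items():
            p = out_dir / f"{name}.csv"
            frame.to_csv(p, index=False)
            written.append(p)
        log = {
            "config_digest": config.digest(),
            "seed": config.seed,
            "inputs": str(in_dir),
            "stages": list(outputs),
            "note": "group statistics are descriptive mean +/- SE; no mixed-model inference",
        }
        (out_dir / "run_log.json").write_text(json.dumps(log, indent=1))
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(f"writing outputs failed: {exc}") from exc
    return outputs


def _season_summary(outputs: dict[str, pd.DataFrame]) -> pd.DataFrame:
    cum = outputs["cumulative"]
    co2 = cum[cum["gas"] == "CO2"].set_index(["plot_id", "year"])["cumulative_kg_ha"]
    n2o = cum[cum["gas"] == "N2O"].set_index(["plot_id", "year"])["cumulative_kg_ha"]
    rows = []
    for _, sw in outputs["season_water"].iterrows():
        key = (sw["plot_id"], sw["year"])
        et_df = outputs["daily_et"]
        sel = et_df[(et_df["plot_id"] == sw["plot_id"]) & (et_df["year"] == sw["year"])]
        excl = sel[sel["source"] == "gap-filled"]["status"].value_counts().to_dict()
        rows.append(
            {
                "plot_id": sw["plot_id"],
                "crop": sw["crop"],
                "year": sw["year"],
                "cumulative_co2_c_kg_ha": float(co2.get(key, np.nan)),
                "cumulative_n2o_n_kg_ha": float(n2o.get(key, np.nan)),
                "cumulative_et_mm": sw["cumulative_et_mm"],
                "agb_kg_ha": sw["agb_kg_ha"],
                "wue_kg_ha_mm": sw["wue_kg_ha_mm"],
                "n_days_measured": sw["n_measured"],
                "n_days_gap_filled": sw["n_gap_filled"],
                "exclusion_reasons": ";".join(f"{k}={v}" for k, v in sorted(excl.items())),
            }
        )
    return pd.DataFrame(rows)


def _recovery_report(outputs: dict[str, pd.DataFrame], truth: dict) -> pd.DataFrame:
    """Compare per-plot-season estimates with the generator's truth log."""
    rows = []

    sm = pd.DataFrame(truth["soil_moisture"])
    sm["year"] = pd.to_datetime(sm["date"]).dt.year
    emergence = {int(y): dt.date.fromisoformat(v) for y, v in truth["emergence"].items()}
    for (plot, year), grp in sm.groupby(["plot_id", "year"]):
        em = emergence[int(year)]
        season = grp[pd.to_datetime(grp["date"]).dt.date >= em]
        true_cum = float(season["true_et_mm"].sum())
        est = outputs["season_water"]
        row = est[(est["plot_id"] == plot) & (est["year"] == year)]
        if row.empty:
            continue
        est_cum = float(row["cumulative_et_mm"].iloc[0])
        rows.append(
            {
                "quantity": "cumulative_et_mm", "plot_id": plot, "year": int(year),
                "truth": true_cum, "estimate": est_cum,
                "pct_error": (est_cum - true_cum) / true_cum * 100.0 if true_cum else np.nan,
            }
        )

    cht = pd.DataFrame(truth["chambers"])
    est_fluxes = outputs["fluxes"].copy()
    est_fluxes["date"] = pd.to_datetime(est_fluxes["date"]).dt.date
    cht["date"] = pd.to_datetime(cht["date"]).dt.date
    merged = est_fluxes.merge(cht, on=["plot_id", "date", "gas"], how="inner")
    for gas, grp in merged.groupby("gas"):
        err = grp["mass_flux_g_m2_d"] - grp["true_flux_g_m2_d"]
        rows.append(
            {
                "quantity": f"flux_{gas}_g_m2_d", "plot_id": "all", "year": 0,
                "truth": float(grp["true_flux_g_m2_d"].mean()),
                "estimate": float(grp["mass_flux_g_m2_d"].mean()),
                "pct_error": float(err.mean() / grp["true_flux_g_m2_d"].mean() * 100.0),
            }
        )

    bt = pd.DataFrame(truth["biomass"])
    est_ab = outputs["biomass_summary"].merge(bt, on=["plot_id", "crop", "year"])
    if len(est_ab):
        err = (est_ab["agb_kg_ha"] - est_ab["true_agb_kg_ha"]) / est_ab["true_agb_kg_ha"]
        rows.append(
            {
                "quantity": "agb_kg_ha", "plot_id": "all", "year": 0,
                "truth": float(est_ab["true_agb_kg_ha"].mean()),
                "estimate": float(est_ab["agb_kg_ha"].mean()),
                "pct_error": float(err.mean() * 100.0),
            }
        )
    return pd.DataFrame(rows)
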
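"""Soil-water-balance evapotranspiration from profile moisture sensors.

The method: volumetric water content (VWC) sensors at several depths are
integrated to total soil moisture (TSM, mm over the profile) with the
trapezoidal rule for nonuniform depth increments; the layer from the
surface to the first sensor takes that sensor's VWC.  Daily ET on a "clean"
day is the midnight-to-midnight storage depletion net of subsurface
drainage, where drainage is inferred from the 0000-0400 h TSM change (no
transpiration or evaporation is expected in that interval):

    q_daily = 24 * max(0, TSM_0000 - TSM_0400) / 4          [mm/day]
    ET_j    = (TSM_j - TSM_{j+1}) - q_daily                 [mm/day]

Days are screened out when storage increased overnight-to-overnight
(net gain), when precipitation fell that day or in the preceding three
days, or when TSM exceeds field capacity (FC, estimated as the mean TSM in
the 30 days before crop emergence, the profile being fully recharged over
winter).  Screened-out days are gap-filled with the most recent measured
ET:PET ratio applied to that day's FAO-56 ET0; leading gaps use the first
available ratio.  Seasonal water-use efficiency is aboveground biomass
divided by cumulative seasonal ET.

Note on the drainage sign: adding q to the storage depletion would count
water that left by gravity as transpired water; the default here subtracts
it.  ``eq1_literal=True`` switches to the additive form for comparison.
On retained days TSM <= FC so q is ~0 and the two conventions nearly
coincide.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

PROFILE_DEPTH_CM = 90.0


class WaterBalanceError(ValueError):
    """Raised for invalid moisture inputs or empty estimation windows."""


# ---------------------------------------------------------------- profile TSM

def profile_tsm(depths_cm, vwc) -> float:
    """Depth-integrated soil moisture (mm) from point VWC readings.

    Surface-to-first-sensor layer: theta at the first sensor extended to
    the surface.  Between sensors: trapezoids on the nonuniform grid.
    """
    d = np.asarray(depths_cm, dtype=float)
    th = np.asarray(vwc, dtype=float)
    if d.size == 0:
        raise WaterBalanceError("no depths supplied")
    if d.size != th.size:
        raise WaterBalanceError("depths and vwc lengths differ")
    order = np.argsort(d)
    d, th = d[order], th[order]
    if np.any(np.diff(d) <= 0):
        raise WaterBalanceError("duplicate sensor depths")
    if np.any(d <= 0):
        raise WaterBalanceError("depths must be positive")
    if np.any((th < 0) | (th > 1)) or not np.all(np.isfinite(th)):
        raise WaterBalanceError("vwc out of [0, 1]")
    total_cm = th[0] * d[0]
    if d.size > 1:
        total_cm += float(np.sum(0.5 * (th[:-1] + th[1:]) * np.diff(d)))
    return total_cm * 10.0  # cm water -> mm


def tsm_series(vwc: pd.DataFrame) -> pd.DataFrame:
    """Per-plot, per-timestamp TSM from a long VWC table.

    ``vwc`` columns: timestamp, plot_id, depth_cm, vwc.
    """
    df = vwc.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    wide = df.pivot_table(
        index=["plot_id", "timestamp"], columns="depth_cm", values="vwc", aggfunc="mean"
    )
    if not wide.isna().any().any():
        # uniform sensor grid: one weighted sum over the trapezoid coefficients
        depths = np.asarray(sorted(wide.columns), dtype=float)
        wide = wide[sorted(wide.columns)]
        theta = wide.to_numpy()
        if np.any((theta < 0) | (theta > 1)) or not np.all(np.isfinite(theta)):
            raise WaterBalanceError("vwc out of [0, 1]")
        coeff = np.empty_like(depths)
        coeff[0] = depths[0] + (0.5 * (depths[1] - depths[0]) if len(depths) > 1 else 0.0)
        if len(depths) > 2:
            coeff[1:-1] = 0.5 * (depths[2:] - depths[:-2])
        if len(depths) > 1:
            coeff[-1] = 0.5 * (depths[-1] - depths[-2])
        tsm = theta @ (coeff * 10.0)
        out = wide.index.to_frame(index=False)
        out["tsm_mm"] = tsm
        return out
    rows = []
    for (plot, ts), grp in df.groupby(["plot_id", "timestamp"], sort=True):
        rows.append(
            {
                "plot_id": plot,
                "timestamp": ts,
                "tsm_mm": profile_tsm(grp["depth_cm"].to_numpy(), grp["vwc"].to_numpy()),
            }
        )
    return pd.DataFrame(rows)


# ------------------------------------------------------------- field capacity

@dataclass(frozen=True)
class FieldCapacity:
    fc_mm: float
    window_start: dt.date
    window_end: dt.date
    n_readings: int
    level: str = "site"      # "site" or a plot id


def estimate_field_capacity(
    tsm: pd.DataFrame,
    emergence: dt.date,
    window_days: int = 30,
    plot_id: str | None = None,
) -> FieldCapacity:
    """Mean TSM over [emergence - window_days, emergence).

    Site-level by default (all plots pooled); pass ``plot_id`` for a
    per-plot estimate.
    """
    df = tsm.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    start = pd.Timestamp(emergence) - pd.Timedelta(days=window_days)
    end = pd.Timestamp(emergence)
    sel = df[(df["timestamp"] >= start) & (df["timestamp"] < end)]
    if plot_id is not None:
        sel = sel[sel["plot_id"] == plot_id]
    if sel.empty:
        raise WaterBalanceError(
            f"no TSM readings in field-capacity window {start.date()}..{emergence}"
        )
    return FieldCapacity(
        fc_mm=float(sel["tsm_mm"].mean()),
        window_start=start.date(),
        window_end=emergence,
        n_readings=int(len(sel)),
        level=plot_id or "site",
    )


# ------------------------------------------------------- daily decomposition

def nightly_drainage(tsm_0000: float, tsm_0400: float) -> float:
    """Daily subsurface drainage q (mm/day) from the 0000-0400 h TSM drop.

    Hourly rate = (TSM_0000 - TSM_0400)/4, clamped at zero (an overnight
    gain is recharge, not drainage), scaled to 24 h.
    """
    rate = max(0.0, (tsm_0000 - tsm_0400) / 4.0)
    return 24.0 * rate


def daily_tsm_anchors(
    tsm: pd.DataFrame,
    plot_id: str,
    tolerance_min: int = 15,
) -> pd.DataFrame:
    """Per-day TSM at the 0000 h and 0400 h anchors for one plot.

    The nearest record within +/- ``tolerance_min`` of each nominal time is
    used; a missing anchor leaves NaN (the day becomes q-unavailable or
    unusable downstream).
    """
    df = tsm[tsm["plot_id"] == plot_id].copy()
    if df.empty:
        raise WaterBalanceError(f"no TSM data for plot {plot_id!r}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df = df.sort_values("timestamp")
    days = pd.date_range(df["timestamp"].dt.normalize().min(),
                         df["timestamp"].dt.normalize().max(), freq="D")
    tol = pd.Timedelta(minutes=tolerance_min)
    ts = df["timestamp"].to_numpy()
    vals = df["tsm_mm"].to_numpy()

    def anchor(nominal: pd.Timestamp) -> float:
        i = np.searchsorted(ts, np.datetime64(nominal))
        best, best_dt = np.nan, tol + pd.Timedelta(seconds=1)
        for j in (i - 1, i):
            if 0 <= j < len(ts):
                delta = abs(pd.Timestamp(ts[j]) - nominal)
                if delta <= tol and delta < best_dt:
                    best, best_dt = vals[j], delta
        return float(best)

    recs = []
    for day in days:
        recs.append(
            {
                "date": day,
                "tsm_0000": anchor(day),
                "tsm_0400": anchor(day + pd.Timedelta(hours=4)),
            }
        )
    out = pd.DataFrame(recs)
    out["tsm_next_0000"] = out["tsm_0000"].shift(-1)
    return out


# ----------------------------------------------------------------- screening

INCLUDED = "included"
NET_GAIN = "net-gain"
PRECIP_WINDOW = "precip-window"
ABOVE_FC = "above-fc"
Q_UNAVAILABLE = "q-unavailable"
NO_DATA = "no-data"
NEGATIVE_ET = "negative-et"

EXCLUSION_PRIORITY = (NET_GAIN, PRECIP_WINDOW, ABOVE_FC)


def screen_days(
    daily: pd.DataFrame,
    precip: pd.DataFrame,
    fc: FieldCapacity,
    precip_lag_days: int = 3,
) -> pd.DataFrame:
    """Attach an inclusion status to each day.

    ``daily``: output of :func:`daily_tsm_anchors` (date, tsm_0000,
    tsm_0400, tsm_next_0000).  ``precip``: date, precip_mm.  Exclusion
    reasons, first match wins: net storage gain overnight-to-overnight;
    precipitation on the day or the preceding ``precip_lag_days`` days;
    TSM above field capacity.  Days missing either midnight anchor are
    ``no-data``; included days missing the 0400 anchor are
    ``q-unavailable``.
    """
    p = precip.copy()
    p["date"] = pd.to_datetime(p["date"])
    pmap = p.set_index("date")["precip_mm"]
    out = daily.copy()
    out["date"] = pd.to_datetime(out["date"])
    if len(pmap.reindex(out["date"]).dropna()) < len(out):
        absent = sorted(set(out["date"]) - set(pmap.index))
        raise WaterBalanceError(
            f"precipitation series missing {len(absent)} day(s), first {absent[0].date()}"
        )

    statuses = []
    for _, row in out.iterrows():
        day = row["date"]
        if np.isnan(row["tsm_0000"]) or np.isnan(row["tsm_next_0000"]):
            statuses.append(NO_DATA)
            continue
        if row["tsm_next_0000"] > row["tsm_0000"]:
            statuses.append(NET_GAIN)
            continue
        wet = any(
            pmap.get(day - pd.Timedelta(days=k), 0.0) > 0.0
            for k in range(0, precip_lag_days + 1)
        )
        if wet:
            statuses.append(PRECIP_WINDOW)
            continue
        if row["tsm_0000"] > fc.fc_mm:
            statuses.append(ABOVE_FC)
            continue
        if np.isnan(row["tsm_0400"]):
            statuses.append(Q_UNAVAILABLE)
            continue
        statuses.append(INCLUDED)
    out["status"] = statuses
    out["precip_mm"] = pmap.reindex(out["date"]).to_numpy()
    return out


def daily_et(
    tsm_j: float,
    tsm_j1: float,
    q: float,
    eq1_literal: bool = False,
) -> float:
    """ET (mm) for one included day from the storage change and drainage.

    Default: et = (TSM_j - TSM_{j+1}) - q.  ``eq1_literal`` adds q instead.
    """
    depletion = tsm_j - tsm_j1
    return depletion + q if eq1_literal else depletion - q


def measured_et(
    screened: pd.DataFrame,
    eq1_literal: bool = False,
) -> pd.DataFrame:
    """Per-day measured ET for included days; negative results demote the
    day to ``negative-et`` (screened out rather than reported)."""
    df = screened.copy()
    ets, statuses = [], []
    for _, row in df.iterrows():
        if row["status"] != INCLUDED:
            ets.append(np.nan)
            statuses.append(row["status"])
            continue
        q = nightly_drainage(row["tsm_0000"], row["tsm_0400"])
        et = daily_et(row["tsm_0000"], row["tsm_next_0000"], q, eq1_literal)
        if et < 0:
            ets.append(np.nan)
            statuses.append(NEGATIVE_ET)
        else:
            ets.append(et)
            statuses.append(INCLUDED)
    df["q_mm"] = [
        nightly_drainage(r["tsm_0000"], r["tsm_0400"])
        if s == INCLUDED and not np.isnan(r["tsm_0400"]) else np.nan
        for s, (_, r) in zip(statuses, df.iterrows())
    ]
    df["et_mm"] = ets
    df["status"] = statuses
    return df


# ---------------------------------------------------------------- gap filling

def gap_fill_et(et: pd.DataFrame, pet: pd.DataFrame) -> pd.DataFrame:
    """Complete the daily ET series with ET:PET-ratio gap filling.

    ``et``: date, et_mm (NaN on excluded days), status.  ``pet``: date,
    et0_mm.  Each excluded day receives (latest prior measured ET/ET0
    ratio) x that day's ET0; days before the first measured ratio use the
    first ratio (backfill).  Output adds ``source`` (measured/gap-filled)
    and ``ratio`` (the ratio applied, NaN for measured days).
    """
    p = pet.copy()
    p["date"] = pd.to_datetime(p["date"])
    pmap = p.set_index("date")["et0_mm"]
    df = et.copy()
    df["date"] = pd.to_datetime(df["date"])
    df = df.sort_values("date").reset_index(drop=True)

    ratios = []
    for _, row in df.iterrows():
        if row["status"] == INCLUDED and not np.isnan(row["et_mm"]):
            pet_day = pmap.get(row["date"], np.nan)
            ratios.append(row["et_mm"] / pet_day if pet_day and pet_day > 0 else np.nan)
        else:
            ratios.append(np.nan)
    ratio_series = pd.Series(ratios).ffill().bfill()
    if ratio_series.isna().all():
        raise WaterBalanceError("no measured ET day with positive PET; cannot gap-fill")

    out_et, sources, used = [], [], []
    for i, row in df.iterrows():
        if row["status"] == INCLUDED and not np.isnan(row["et_mm"]):
            out_et.append(row["et_mm"])
            sources.append("measured")
            used.append(np.nan)
        else:
            pet_day = pmap.get(row["date"])
            if pet_day is None or np.isnan(pet_day):
                raise WaterBalanceError(f"no PET available for {row['date'].date()}")
            r = float(ratio_series.iloc[i])
            out_et.append(r * float(pet_day))
            sources.append("gap-filled")
            used.append(r)
    df["et_mm"] = out_et
    df["source"] = sources
    df["ratio"] = used
    return df


# ------------------------------------------------------------ season summary

@dataclass(frozen=True)
class SeasonWater:
    plot_id: str
    season: str
    cumulative_et_mm: float
    agb_kg_ha: float
    wue_kg_ha_mm: float | None    # None when cumulative ET is 0 and AGB > 0
    n_measured: int
    n_gap_filled: int


def season_water_summary(
    et: pd.DataFrame,
    agb_kg_ha: float,
    window_start: dt.date,
    window_end: dt.date,
    plot_id: str = "",
    season: str = "",
) -> SeasonWater:
    """Cumulative seasonal ET and water-use efficiency (AGB / cumulative ET)."""
    if agb_kg_ha < 0:
        raise WaterBalanceError("negative AGB")
    df = et.copy()
    df["date"] = pd.to_datetime(df["date"])
    sel = df[(df["date"] >= pd.Timestamp(window_start)) & (df["date"] <= pd.Timestamp(window_end))]
    if sel.empty:
        raise WaterBalanceError(f"ET series does not cover {window_start}..{window_end}")
    cum = float(sel["et_mm"].sum())
    if cum > 0:
        wue = agb_kg_ha / cum
    elif agb_kg_ha == 0:
        wue = 0.0
    else:
        wue = None
    return SeasonWater(
        plot_id=plot_id, season=season, cumulative_et_mm=cum, agb_kg_ha=agb_kg_ha,
        wue_kg_ha_mm=wue,
        n_measured=int((sel["source"] == "measured").sum()),
        n_gap_filled=int((sel["source"] == "gap-filled").sum()),
    )


# -------------------------------------------------------------- orchestrator

def plot_daily_et(
    tsm: pd.DataFrame,
    precip: pd.DataFrame,
    pet: pd.DataFrame,
    plot_id: str,
    emergence: dt.date,
    window_start: dt.date,
    window_end: dt.date,
    fc: FieldCapacity | None = None,
    eq1_literal: bool = False,
    precip_lag_days: int = 3,
) -> tuple[pd.DataFrame, FieldCapacity]:
    """Full screened + gap-filled daily ET series for one plot-season."""
    if fc is None:
        fc = estimate_field_capacity(tsm, emergence)
    anchors = daily_tsm_anchors(tsm, plot_id)
    anchors = anchors[
        (anchors["date"] >= pd.Timestamp(window_start))
        & (anchors["date"] <= pd.Timestamp(window_end))
    ].reset_index(drop=True)
    if anchors.empty:
        raise WaterBalanceError(
            f"plot {plot_id}: no TSM days inside {window_start}..{window_end}"
        )
    screened = screen_days(anchors, precip, fc, precip_lag_days)
    measured = measured_et(screened, eq1_literal)
    filled = gap_fill_et(measured, pet)
    filled.insert(0, "plot_id", plot_id)
    return filled, fc
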
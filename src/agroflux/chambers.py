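"""Static-chamber soil gas fluxes: slope fitting, ideal-gas conversion,
daily interpolation and seasonal cumulation.

A closed chamber placed on a soil anchor accumulates (or loses) gas; the
headspace mole-fraction trend over the deployment, combined with the
ideal-gas headspace inventory, yields the soil-atmosphere flux:

    F_molar = (dC/dt * 1e-6) * P * V / (R * T) / A      [mol m-2 s-1]

with dC/dt the OLS slope in ppm/s, P headspace pressure (Pa), V headspace
volume (m3), T air temperature (K), A basal area (m2).  Fluxes are reported
as element mass (CO2-C or N2O-N) per day; N2O carries two N per molecule.
Negative fluxes (uptake) are retained.

Between sampling dates daily fluxes are linearly interpolated; cumulative
seasonal emissions are the sum of daily values converted to kg element per
hectare (1 g m-2 = 10 kg ha-1).  No extrapolation happens outside the
first/last observation: the cumulation window is clipped to the observed
span and the clipping is reported.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

R_GAS = 8.314462618  # J mol-1 K-1

# grams of reported element per mole of gas
ELEMENT_MASS = {
    "CO2": 12.011,        # C
    "N2O": 2 * 14.007,    # N2O-N: two nitrogen atoms
}

SECONDS_PER_DAY = 86400.0
G_M2_TO_KG_HA = 10.0


class ChamberError(ValueError):
    """Raised for invalid chamber series or geometry."""


@dataclass(frozen=True)
class ChamberGeometry:
    """Anchor + dome geometry. The dome is irregular, so headspace volume is
    a supplied constant rather than derived from the cylinder."""

    diameter: float = 0.203   # m, internal
    height: float = 0.065     # m, aboveground anchor height
    volume: float = 0.005     # m3, total headspace

    def __post_init__(self) -> None:
        if min(self.diameter, self.height, self.volume) <= 0:
            raise ChamberError("geometry fields must be positive")

    @property
    def area(self) -> float:
        """Basal (soil) area, m2."""
        return math.pi * (self.diameter / 2.0) ** 2


@dataclass(frozen=True)
class ConcentrationSeries:
    """One chamber deployment's timed mole fractions."""

    plot_id: str
    chamber_id: str
    date: dt.date
    gas: str
    elapsed_s: np.ndarray
    ppm: np.ndarray
    air_temp_k: float
    pressure_pa: float

    def __post_init__(self) -> None:
        t = np.asarray(self.elapsed_s, dtype=float)
        c = np.asarray(self.ppm, dtype=float)
        object.__setattr__(self, "elapsed_s", t)
        object.__setattr__(self, "ppm", c)
        if self.gas not in ELEMENT_MASS:
            raise ChamberError(f"unknown gas {self.gas!r}")
        if t.size < 3:
            raise ChamberError(f"{self.chamber_id} {self.date}: need >= 3 points, got {t.size}")
        if t.size != c.size:
            raise ChamberError("elapsed_s and ppm lengths differ")
        if np.any(np.diff(t) <= 0):
            raise ChamberError("elapsed times must be strictly increasing")
        if np.any(c <= 0) or not np.all(np.isfinite(c)):
            raise ChamberError("mole fractions must be positive and finite")
        if self.air_temp_k <= 0 or self.pressure_pa <= 0:
            raise ChamberError("temperature and pressure must be positive")


@dataclass(frozen=True)
class FluxEstimate:
    """Per-deployment flux with QC provenance."""

    plot_id: str
    chamber_id: str
    date: dt.date
    gas: str
    slope_ppm_s: float
    r_squared: float
    molar_flux: float          # mol m-2 s-1
    mass_flux: float           # g element m-2 day-1
    qc_flags: tuple[str, ...] = field(default_factory=tuple)


def fit_concentration_slope(series: ConcentrationSeries) -> tuple[float, float]:
    """OLS slope (ppm/s) and r2 of mole fraction vs elapsed time.

    All points are used; no deadband removal, no nonlinear correction.
    A perfectly flat series has slope 0 and r2 0 (no explained variance).
    """
    t, c = series.elapsed_s, series.ppm
    if np.ptp(t) == 0:
        raise ChamberError("zero time variance")
    res = stats.linregress(t, c)
    r2 = 0.0 if np.isnan(res.rvalue) else float(res.rvalue) ** 2
    return float(res.slope), r2


def slope_to_mass_flux(
    slope_ppm_s: float,
    geom: ChamberGeometry,
    air_temp_k: float,
    pressure_pa: float,
    gas: str,
) -> tuple[float, float]:
    """Ideal-gas conversion of a concentration slope to fluxes.

    Returns (molar flux mol m-2 s-1, element-mass flux g m-2 day-1);
    both share the slope's sign.
    """
    if air_temp_k <= 0 or pressure_pa <= 0:
        raise ChamberError("temperature and pressure must be positive")
    if gas not in ELEMENT_MASS:
        raise ChamberError(f"unknown gas {gas!r}")
    headspace_mol = pressure_pa * geom.volume / (R_GAS * air_temp_k)
    molar = slope_ppm_s * 1e-6 * headspace_mol / geom.area
    mass = molar * ELEMENT_MASS[gas] * SECONDS_PER_DAY
    return molar, mass


def estimate_flux(
    series: ConcentrationSeries,
    geom: ChamberGeometry,
    r2_threshold: float = 0.7,
    slope_threshold_ppm_s: float | None = None,
) -> FluxEstimate:
    """Fit, convert and QC-flag one deployment.

    Low r2 alone is not grounds for rejection: a genuinely near-zero flux
    produces a flat, noise-dominated trace.  A deployment is flagged
    (``low-r2``) only when r2 < ``r2_threshold`` AND the slope magnitude
    exceeds ``slope_threshold_ppm_s``; flagged fluxes are retained.
    """
    slope, r2 = fit_concentration_slope(series)
    molar, mass = slope_to_mass_flux(
        slope, geom, series.air_temp_k, series.pressure_pa, series.gas
    )
    if slope_threshold_ppm_s is None:
        # default: ~1 ppm over the 5-min deployment
        slope_threshold_ppm_s = 1.0 / 300.0
    flags: list[str] = []
    if r2 < r2_threshold and abs(slope) > slope_threshold_ppm_s:
        flags.append("low-r2")
    return FluxEstimate(
        plot_id=series.plot_id, chamber_id=series.chamber_id, date=series.date,
        gas=series.gas, slope_ppm_s=slope, r_squared=r2,
        molar_flux=molar, mass_flux=mass, qc_flags=tuple(flags),
    )


def flux_frame(estimates: list[FluxEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "plot_id": [e.plot_id for e in estimates],
            "chamber_id": [e.chamber_id for e in estimates],
            "date": [e.date for e in estimates],
            "gas": [e.gas for e in estimates],
            "slope_ppm_s": [e.slope_ppm_s for e in estimates],
            "r_squared": [e.r_squared for e in estimates],
            "molar_flux_mol_m2_s": [e.molar_flux for e in estimates],
            "mass_flux_g_m2_d": [e.mass_flux for e in estimates],
            "qc_flags": [";".join(e.qc_flags) for e in estimates],
        }
    )


def interpolate_daily_flux(observations: pd.DataFrame) -> pd.DataFrame:
    """Daily flux series per plot and gas by linear interpolation.

    ``observations`` columns: plot_id, gas, date, mass_flux_g_m2_d.
    Same-day replicate chambers within a plot are averaged first.  Values
    are produced only inside [first, last] observation date (no
    extrapolation); a single observation yields a one-day series.
    """
    if observations.empty:
        raise ChamberError("no flux observations to interpolate")
    obs = observations.copy()
    obs["date"] = pd.to_datetime(obs["date"])
    out_parts = []
    for (plot, gas), grp in obs.groupby(["plot_id", "gas"], sort=True):
        daily_obs = grp.groupby("date", as_index=False)["mass_flux_g_m2_d"].mean()
        daily_obs = daily_obs.sort_values("date")
        days = pd.date_range(daily_obs["date"].iloc[0], daily_obs["date"].iloc[-1], freq="D")
        x = daily_obs["date"].map(pd.Timestamp.toordinal).to_numpy(float)
        y = daily_obs["mass_flux_g_m2_d"].to_numpy(float)
        vals = np.interp([d.toordinal() for d in days], x, y)
        out_parts.append(
            pd.DataFrame({"plot_id": plot, "gas": gas, "date": days, "mass_flux_g_m2_d": vals})
        )
    return pd.concat(out_parts, ignore_index=True)


@dataclass(frozen=True)
class CumulativeEmission:
    plot_id: str
    gas: str
    window_label: str
    start: dt.date            # effective (clipped) start
    end: dt.date              # effective (clipped) end
    cumulative_kg_ha: float
    n_days: int
    clipped: bool             # True when the window exceeded the observed span


def cumulate_emissions(
    daily: pd.DataFrame,
    window_start: dt.date,
    window_end: dt.date,
    label: str = "season",
) -> list[CumulativeEmission]:
    """Cumulative emissions per plot and gas over a window.

    The window is clipped to each plot's observed daily span; an empty
    intersection raises.  Units: daily g m-2 day-1 summed, then 10x to
    kg element ha-1.
    """
    df = daily.copy()
    df["date"] = pd.to_datetime(df["date"])
    ws, we = pd.Timestamp(window_start), pd.Timestamp(window_end)
    out = []
    for (plot, gas), grp in df.groupby(["plot_id", "gas"], sort=True):
        lo, hi = grp["date"].min(), grp["date"].max()
        eff_lo, eff_hi = max(ws, lo), min(we, hi)
        if eff_lo > eff_hi:
            raise ChamberError(
                f"plot {plot} {gas}: window {window_start}..{window_end} does not "
                f"intersect observed span {lo.date()}..{hi.date()}"
            )
        sel = grp[(grp["date"] >= eff_lo) & (grp["date"] <= eff_hi)]
        total_g_m2 = float(sel["mass_flux_g_m2_d"].sum())
        out.append(
            CumulativeEmission(
                plot_id=plot, gas=gas, window_label=label,
                start=eff_lo.date(), end=eff_hi.date(),
                cumulative_kg_ha=total_g_m2 * G_M2_TO_KG_HA,
                n_days=int(len(sel)),
                clipped=bool(eff_lo > ws or eff_hi < we),
            )
        )
    return out


def cumulative_frame(emissions: list[CumulativeEmission]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "plot_id": [e.plot_id for e in emissions],
            "gas": [e.gas for e in emissions],
            "window": [e.window_label for e in emissions],
            "start": [e.start for e in emissions],
            "end": [e.end for e in emissions],
            "cumulative_kg_ha": [e.cumulative_kg_ha for e in emissions],
            "n_days": [e.n_days for e in emissions],
            "clipped": [e.clipped for e in emissions],
        }
    )
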
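"""Yield, biomass and soil-carbon derivations.

Covers the harvest arithmetic around the flux and water-balance pipeline:
moisture-adjusted dry yields scaled to kg/ha, corn aboveground biomass
from grain via the standard harvest index (grain / AGB = 0.545), root
profile totals and per-depth fractions over 0-90 cm, and soil carbon
stocks from concentration x bulk density x layer thickness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CORN_HARVEST_INDEX = 0.545
M2_PER_HA = 10_000.0


class BiomassError(ValueError):
    pass


@dataclass(frozen=True)
class HarvestRecord:
    plot_id: str
    crop: str
    fresh_mass_kg: float
    moisture_pct: float        # wet basis
    area_m2: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.moisture_pct <= 100.0:
            raise BiomassError(f"moisture {self.moisture_pct}% out of [0, 100]")
        if self.area_m2 <= 0:
            raise BiomassError("sampled area must be positive")
        if self.fresh_mass_kg < 0:
            raise BiomassError("negative fresh mass")


def dry_matter_yield(record: HarvestRecord) -> float:
    """Dry yield, kg/ha: fresh x (1 - moisture/100) / area x 10,000."""
    return record.fresh_mass_kg * (1.0 - record.moisture_pct / 100.0) / record.area_m2 * M2_PER_HA


def corn_agb_from_grain(dry_grain_kg_ha: float, harvest_index: float = CORN_HARVEST_INDEX) -> float:
    """Total aboveground biomass from dry grain yield via the harvest index."""
    if dry_grain_kg_ha < 0:
        raise BiomassError("negative grain yield")
    if not 0.0 < harvest_index <= 1.0:
        raise BiomassError(f"harvest index {harvest_index} out of (0, 1]")
    return dry_grain_kg_ha / harvest_index


def _validate_profile(profile: pd.DataFrame) -> pd.DataFrame:
    df = profile.sort_values("depth_top_cm").reset_index(drop=True)
    if (df["kg_ha"] < 0).any():
        raise BiomassError("negative root biomass increment")
    if (df["depth_bottom_cm"] <= df["depth_top_cm"]).any():
        raise BiomassError("inverted depth interval")
    tops = df["depth_top_cm"].to_numpy()
    bottoms = df["depth_bottom_cm"].to_numpy()
    if tops[0] != 0 or not np.array_equal(tops[1:], bottoms[:-1]):
        raise BiomassError("depth intervals must be contiguous from the surface")
    return df


def summarize_root_profile(profiles: pd.DataFrame) -> pd.DataFrame:
    """Totals and per-depth fractions per crop.

    ``profiles`` columns: crop, depth_top_cm, depth_bottom_cm, kg_ha.
    Totals are always recomputed from the increments (never taken from a
    printed total row).  Fractions require a positive total.
    """
    rows = []
    for crop, grp in profiles.groupby("crop", sort=True):
        df = _validate_profile(grp)
        total = float(df["kg_ha"].sum())
        if total <= 0:
            raise BiomassError(f"{crop}: zero total root biomass, fractions undefined")
        for _, r in df.iterrows():
            rows.append(
                {
                    "crop": crop,
                    "depth_top_cm": r["depth_top_cm"],
                    "depth_bottom_cm": r["depth_bottom_cm"],
                    "kg_ha": float(r["kg_ha"]),
                    "total_kg_ha": total,
                    "fraction": float(r["kg_ha"]) / total,
                }
            )
    return pd.DataFrame(rows)


def root_total(profiles: pd.DataFrame, crop: str) -> float:
    """0-90 cm root biomass total for one crop, kg/ha."""
    summary = summarize_root_profile(profiles[profiles["crop"] == crop])
    return float(summary["total_kg_ha"].iloc[0])


def crop_total_ratio(profiles: pd.DataFrame, numerator_crop: str, denominator_crop: str) -> float:
    return root_total(profiles, numerator_crop) / root_total(profiles, denominator_crop)


def soil_c_stock(
    concentration_g_kg: float,
    bulk_density_g_cm3: float,
    depth_top_cm: float,
    depth_bottom_cm: float,
) -> float:
    """Layer soil-carbon stock, Mg C/ha.

    stock = C (g/kg) x BD (g/cm3) x thickness (cm) x 0.1, the 0.1 folding
    the g->Mg and cm2->ha conversions.
    """
    if depth_bottom_cm <= depth_top_cm:
        raise BiomassError("inverted depth interval")
    if concentration_g_kg < 0 or bulk_density_g_cm3 <= 0:
        raise BiomassError("invalid concentration or bulk density")
    return concentration_g_kg * bulk_density_g_cm3 * (depth_bottom_cm - depth_top_cm) * 0.1
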
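"""Packaged reference tables for the Urbana, IL field site.

Two small published summaries ship with the package: the monthly climate
normals/observations for the 2020-2022 study period at the
Champaign-Urbana station, and the end-of-study root-biomass and soil-carbon
depth profile for the two crops.  They serve as worked-example inputs for
the aggregation and biomass arithmetic.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("agroflux.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def urbana_monthly_climate() -> pd.DataFrame:
    """Monthly mean temperature (deg C) and precipitation (mm), 2020-2022."""
    return _load("urbana_monthly_climate.csv")


def urbana_root_profiles() -> pd.DataFrame:
    """Root biomass (kg/ha) and soil total C (g/kg) by depth increment.

    Columns: crop, depth_top_cm, depth_bottom_cm, root_kg_ha, soil_c_g_kg.
    Totals are deliberately not included; recompute them from increments.
    """
    return _load("urbana_root_biomass.csv")
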
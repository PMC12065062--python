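"""Pore-water nitrate summaries.

Suction samplers below the root zone capture leachate whose NO3-N
concentration (mg/L) indicates nitrate moving toward groundwater.  This
module reduces the sample table to descriptive group statistics
(mean +/- SE, n) by crop x year x depth and computes relative reductions
between crops.  Replicate samplers within a plot-date are averaged first
(configurable), mirroring the chamber-replicate handling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class LeachateError(ValueError):
    pass


REQUIRED_COLUMNS = ("date", "plot_id", "crop", "depth_cm", "no3n_mg_l")


def _prepare(samples: pd.DataFrame, average_replicates: bool) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in samples.columns]
    if missing:
        raise LeachateError(f"missing columns: {missing}")
    df = samples.copy()
    if (df["no3n_mg_l"] < 0).any():
        raise LeachateError("negative NO3-N concentration")
    df["date"] = pd.to_datetime(df["date"])
    df["year"] = df["date"].dt.year
    if average_replicates:
        df = (
            df.groupby(["date", "year", "plot_id", "crop", "depth_cm"], as_index=False)
            ["no3n_mg_l"].mean()
        )
    return df


def summarize_no3(
    samples: pd.DataFrame,
    by: tuple[str, ...] = ("crop", "year", "depth_cm"),
    average_replicates: bool = True,
) -> pd.DataFrame:
    """Mean, SE (= sd/sqrt(n)) and n of NO3-N per group."""
    df = _prepare(samples, average_replicates)
    grp = df.groupby(list(by))["no3n_mg_l"]
    out = grp.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    out["sd"] = out["sd"].fillna(0.0)  # single-sample group: no spread estimate
    out["se"] = out["sd"] / np.sqrt(out["n"])
    return out.drop(columns="sd")


def relative_reduction(mean_ref: float, mean_alt: float) -> float:
    """Percent reduction of ``mean_alt`` relative to ``mean_ref``."""
    if mean_ref == 0:
        raise LeachateError("reference mean is zero; reduction undefined")
    return (mean_ref - mean_alt) / mean_ref * 100.0


def crop_reduction_by_year(
    samples: pd.DataFrame,
    reference_crop: str,
    alternative_crop: str,
    average_replicates: bool = True,
) -> pd.DataFrame:
    """Yearly percent reduction of the alternative crop vs the reference,
    averaged across depths."""
    summary = summarize_no3(samples, by=("crop", "year"), average_replicates=average_replicates)
    rows = []
    for year, grp in summary.groupby("year"):
        means = grp.set_index("crop")["mean"]
        if reference_crop not in means.index or alternative_crop not in means.index:
            continue
        rows.append(
            {
                "year": year,
                "mean_reference": float(means[reference_crop]),
                "mean_alternative": float(means[alternative_crop]),
                "reduction_pct": relative_reduction(
                    float(means[reference_crop]), float(means[alternative_crop])
                ),
            }
        )
    if not rows:
        raise LeachateError("no year has both crops sampled")
    return pd.DataFrame(rows)
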
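"""Spatial and temporal aggregation of climate input.

Each plot-year of a simulation receives exactly one climate record; the
aggregation scheme decides how it is built from the plot-level series:

* spatial scale — ``plot`` (as observed), ``district`` or ``country``
  (unweighted means of each climate variable over the member plots);
* temporal scale — ``annual`` (each year its own record), ``fiveyear``
  (mean over the years between consecutive plot inventories, windows
  anchored on each plot's own inventory cycle and extended backwards over
  the pre-simulation period), or ``longterm`` (the fixed 1991-2008 mean
  applied to every year).

Because the climate-dependence factor is nonlinear (concave in
precipitation below its asymptote, convex in temperature), aggregation
does not commute with the factor: the factor of a mean climate differs
systematically from the mean of plot-level factors (a Jensen effect), which
is exactly the behaviour the experiment module quantifies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import climate_modifier_vec
from .params import ParameterSet

__all__ = ["SPATIAL_SCALES", "TEMPORAL_SCALES", "aggregate_climate",
           "spinup_normal", "dependence_factor_summary",
           "LONGTERM_WINDOW", "NORMAL_WINDOW"]

SPATIAL_SCALES = ("plot", "district", "country")
TEMPORAL_SCALES = ("longterm", "fiveyear", "annual")

LONGTERM_WINDOW = (1991, 2008)   # recent long-term mean for constant-climate runs
NORMAL_WINDOW = (1961, 1990)     # climate normal used for spin-up

_VARS = ["mat", "t_min", "t_max", "precip_mm"]


def _check_scales(spatial: str, temporal: str | None = None) -> None:
    if spatial not in SPATIAL_SCALES:
        raise ValueError(f"spatial scale must be one of {SPATIAL_SCALES}")
    if temporal is not None and temporal not in TEMPORAL_SCALES:
        raise ValueError(f"temporal scale must be one of {TEMPORAL_SCALES}")


def _spatial_means(merged: pd.DataFrame, spatial: str) -> pd.DataFrame:
    if spatial == "plot":
        return merged
    key = ["district", "year"] if spatial == "district" else ["year"]
    merged = merged.copy()
    merged[_VARS] = merged.groupby(key)[_VARS].transform("mean")
    return merged


def _validate_coverage(merged: pd.DataFrame, plots: pd.DataFrame) -> None:
    if merged["district"].isna().any():
        bad = merged.loc[merged["district"].isna(), "plot_id"].unique()
        raise ValueError(f"plots without a district: {list(bad)[:10]}")
    absent = set(plots["plot_id"]) - set(merged["plot_id"])
    if absent:
        raise ValueError(f"plots without climate series: {sorted(absent)[:10]}")
    span = np.arange(merged["year"].min(), merged["year"].max() + 1)
    counts = merged.groupby("plot_id")["year"].nunique()
    short = counts[counts < span.size]
    if len(short):
        gaps = {}
        for pid in short.index[:5]:
            have = set(merged.loc[merged["plot_id"] == pid, "year"])
            gaps[pid] = sorted(set(span) - have)[:10]
        raise ValueError(f"missing climate years per plot: {gaps}")


def aggregate_climate(plots: pd.DataFrame, climate: pd.DataFrame,
                      spatial: str, temporal: str) -> pd.DataFrame:
    """Per plot-year climate under one spatial x temporal scheme.

    Returns one row per (plot_id, year) over the full span of ``climate``
    with columns mat, t_min, t_max, precip_mm.
    """
    _check_scales(spatial, temporal)
    merged = climate.merge(plots[["plot_id", "district", "first_year"]],
                           on="plot_id", how="inner", validate="many_to_one")
    _validate_coverage(merged, plots)
    merged = _spatial_means(merged, spatial)

    if temporal == "annual":
        out = merged
    elif temporal == "fiveyear":
        # windows of 5 years anchored one year after each inventory year,
        # extended backwards over the pre-simulation with the same phase
        block = (merged["year"] - merged["first_year"] - 1) // 5
        merged = merged.copy()
        merged[_VARS] = merged.groupby(["plot_id", block])[_VARS].transform("mean")
        out = merged
    else:  # longterm
        lo, hi = LONGTERM_WINDOW
        window = merged[(merged["year"] >= lo) & (merged["year"] <= hi)]
        if window.empty:
            raise ValueError(f"climate series does not cover {lo}-{hi}")
        ref = window.groupby("plot_id")[_VARS].mean()
        out = merged.drop(columns=_VARS).join(ref, on="plot_id")

    return out[["plot_id", "year", *_VARS]].reset_index(drop=True)


def spinup_normal(plots: pd.DataFrame, climate: pd.DataFrame,
                  spatial: str = "plot") -> pd.DataFrame:
    """Per-plot 1961-1990 climate normal at the given spatial scale.

    The spin-up always uses the 30-year normal (never 5-year or annual
    values); only the spatial scale of the simulation applies to it.
    """
    _check_scales(spatial)
    merged = climate.merge(plots[["plot_id", "district"]], on="plot_id",
                           how="inner", validate="many_to_one")
    lo, hi = NORMAL_WINDOW
    window = merged[(merged["year"] >= lo) & (merged["year"] <= hi)]
    if window.empty:
        raise ValueError(f"climate series does not cover the {lo}-{hi} normal")
    window = _spatial_means(window, spatial)
    return window.groupby("plot_id")[_VARS].mean().reset_index()


def dependence_factor_summary(plots: pd.DataFrame, assigned: pd.DataFrame,
                              params: ParameterSet,
                              use_sinusoid: bool = False):
    """Climate-dependence factors per plot-year plus regional summaries.

    Returns ``(factors, by_region, by_period)``: the per plot-year factor
    table, summaries (median/mean/min/max) per region over all plot-years,
    and regional medians per 5-year calendar period.
    """
    fac = assigned.merge(plots[["plot_id", "region"]], on="plot_id",
                         how="left", validate="many_to_one")
    fac["factor"] = climate_modifier_vec(
        fac["mat"].to_numpy(), fac["t_min"].to_numpy(),
        fac["t_max"].to_numpy(), fac["precip_mm"].to_numpy(),
        params, use_sinusoid)
    stats = ["median", "mean", "min", "max"]
    by_region = fac.groupby("region")["factor"].agg(stats).reset_index()
    fac["period"] = (fac["year"] // 5) * 5
    by_period = (fac.groupby(["region", "period"])["factor"]
                 .median().reset_index(name="median_factor"))
    return fac[["plot_id", "year", "region", "factor"]], by_region, by_period
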
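"""The factorial aggregation experiment.

Five named simulations share litter input and differ only in how climate
input is aggregated:

=====  ========  =========  =======================================
name   spatial   temporal   description
=====  ========  =========  =======================================
I      plot      longterm   standard (reporting configuration)
II     district  longterm   effect of spatial scale
III    country   longterm   effect of spatial scale
IV     plot      fiveyear   effect of temporal scale
V      plot      annual     effect of temporal scale
=====  ========  =========  =======================================

Litter input is never aggregated; only the climate driving decomposition
is. Each run spins every plot up to steady state under the 1961-1990
normal (at the simulation's spatial scale), plays the reconstructed
historical litter through the pre-simulation years, then the inventory-
based series to the end year, and records per-plot total-stock
trajectories. Stocks are kg C m^-2; stock changes kg C m^-2 per 5 years;
national change is scaled by each plot's representation area to Gg C yr^-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import aggregation
from .core import climate_modifier_vec, size_modifier
from .initialization import (RulesConfig, back_cast_inputs, group_mean_inputs,
                             steady_state_pools)
from .litter import (AwenTable, BiomassComponents, TurnoverTable,
                     annual_litter, cohorts_to_input)
from .params import SIZE_CLASSES, ParameterSet, default_parameters
from .propagator import AnnualPropagator

__all__ = ["NAMED_SIMULATIONS", "SimulationConfig", "SimulationResult",
           "filter_upland", "run_simulation", "national_change", "report",
           "row_to_components", "build_litter_series"]

NAMED_SIMULATIONS = {
    "I": ("plot", "longterm"),
    "II": ("district", "longterm"),
    "III": ("country", "longterm"),
    "IV": ("plot", "fiveyear"),
    "V": ("plot", "annual"),
}

ORG_LAYER_LIMIT_M = 0.4
KG_M2_TIMES_HA_TO_GG = 1e4 / 1e6  # kg C m^-2 x ha -> Gg C


@dataclass(frozen=True)
class SimulationConfig:
    """One cell of the factorial design.

    Combinations outside the five named simulations must be flagged as
    extensions explicitly.
    """

    spatial: str
    temporal: str
    name: str | None = None
    extension: bool = False
    use_sinusoid: bool = False
    end_year: int = 2012

    def __post_init__(self) -> None:
        if (self.spatial, self.temporal) in NAMED_SIMULATIONS.values():
            named = next(k for k, v in NAMED_SIMULATIONS.items()
                         if v == (self.spatial, self.temporal))
            if self.name is None:
                object.__setattr__(self, "name", named)
        elif not self.extension:
            raise ValueError(
                f"({self.spatial}, {self.temporal}) is not one of the named "
                "simulations; pass extension=True to run it anyway")
        aggregation._check_scales(self.spatial, self.temporal)

    @classmethod
    def named(cls, name: str, **kwargs) -> "SimulationConfig":
        spatial, temporal = NAMED_SIMULATIONS[name]
        return cls(spatial=spatial, temporal=temporal, name=name, **kwargs)


@dataclass
class SimulationResult:
    config: SimulationConfig
    years: np.ndarray                 # global year axis
    plots: pd.DataFrame
    stocks: pd.DataFrame              # index plot_id, columns years; NaN before start
    initial_stock: pd.Series          # steady-state stock per plot (start of presim)

    def mean_stock(self, period: tuple[int, int] = (2008, 2012)) -> float:
        cols = [y for y in self.years if period[0] <= y <= period[1]]
        return float(self.stocks[cols].mean(axis=1).mean())

    def district_stock_means(self, period=(2008, 2012)) -> pd.Series:
        cols = [y for y in self.years if period[0] <= y <= period[1]]
        per_plot = self.stocks[cols].mean(axis=1)
        return per_plot.groupby(self.plots.set_index("plot_id")["district"]).mean()

    def stock_change(self, period=(2000, 2012)) -> pd.Series:
        """Per-plot stock change over the period, kg C m^-2."""
        return self.stocks[period[1]] - self.stocks[period[0]]

    def annual_changes(self) -> pd.DataFrame:
        """Per-plot year-on-year stock change, kg C m^-2 yr^-1.

        The first simulated year of each plot is measured against its
        spin-up steady state.
        """
        filled = self.stocks.copy()
        diff = filled.diff(axis=1)
        first_cols = filled.notna().idxmax(axis=1)
        for pid, col in first_cols.items():
            diff.loc[pid, col] = filled.loc[pid, col] - self.initial_stock[pid]
        return diff

    def national_change_gg(self) -> pd.Series:
        """National stock-change series, Gg C yr^-1."""
        return national_change(self.annual_changes(),
                               self.plots.set_index("plot_id")["area_ha"])

    def cumulative_national_change_gg(self) -> float:
        return float(self.national_change_gg().sum())


def filter_upland(plots: pd.DataFrame) -> pd.DataFrame:
    """Plots on mineral soil: organic-layer thickness strictly < 0.4 m."""
    if "org_layer_m" not in plots:
        raise ValueError("plots table lacks org_layer_m")
    return plots[plots["org_layer_m"] < ORG_LAYER_LIMIT_M].reset_index(drop=True)


def national_change(per_plot_changes: pd.DataFrame | pd.Series,
                    areas_ha: pd.Series):
    """Scale per-plot changes (kg C m^-2 yr^-1) by representation areas.

    Returns Gg C yr^-1: a Series per year if given a plot x year frame,
    else a scalar.
    """
    areas = areas_ha.reindex(per_plot_changes.index)
    if areas.isna().any():
        raise ValueError("area missing for some plots (unit/index mismatch)")
    if (areas <= 0).any():
        raise ValueError("representation areas must be > 0")
    weighted = per_plot_changes.mul(areas * KG_M2_TIMES_HA_TO_GG, axis=0)
    return weighted.sum(skipna=True) if isinstance(per_plot_changes, pd.DataFrame) \
        else float(weighted.sum())


# ---------------------------------------------------------------------------
# litter series assembly

def row_to_components(row: pd.Series) -> BiomassComponents:
    """Biomass table row -> :class:`BiomassComponents`."""
    return BiomassComponents(
        foliage=row["foliage"], branches=row["branches"], stem=row["stem"],
        stump=row["stump"], coarse_roots=row["coarse_roots"],
        fine_roots=row["fine_roots"],
        ground_veg_above={
            "moss": row["gv_moss"], "lichen": row["gv_lichen"],
            "herbs_grasses": row["gv_herbs_grasses"],
            "dwarf_shrubs": row["gv_dwarf_shrubs"]},
    )


def build_litter_series(plots: pd.DataFrame, biomass: pd.DataFrame,
                        turnover: TurnoverTable, awen: AwenTable,
                        rules: RulesConfig, end_year: int = 2012):
    """Annual litter input arrays for every plot over the global year axis.

    Returns ``(years, L, first_inputs)`` with ``L`` of shape
    (n_plots, n_years, 3 size classes, 5 pools); entries before a plot's
    pre-simulation start are zero. ``first_inputs`` is the plot's
    first-inventory living+mortality litter, the basis of the spin-up
    group means. Litter is constant within each 5-year inventory cycle;
    harvest residues of a cycle are spread evenly over its 5 years.
    """
    start = int(plots["first_year"].min()) - rules.presim_years
    years = np.arange(start, end_year + 1)
    n = len(plots)
    L = np.zeros((n, years.size, 3, 5))
    first_inputs = np.zeros((n, 3, 5))
    bm = biomass.set_index(["plot_id", "year"]).sort_index()

    for i, plot in enumerate(plots.to_dict("records")):
        pid = plot["plot_id"]
        species = plot["species"]
        first_year = int(plot["first_year"])
        try:
            plot_bm = bm.loc[pid]
        except KeyError:
            raise ValueError(f"no biomass rows for plot {pid}") from None
        cycle_years = plot_bm.index.to_numpy()
        if first_year not in cycle_years:
            raise ValueError(f"plot {pid}: missing first-inventory biomass "
                             f"({first_year})")
        # pre-simulation: reconstructed history
        psr = pd.Series(plot)
        first_row = plot_bm.loc[first_year]
        presim_years, presim_arr = back_cast_inputs(
            psr, row_to_components(first_row), rules,
            turnover, awen)
        idx = presim_years - start
        L[i, idx] = presim_arr
        # current series: cycle-constant litter from registrations
        cycle_cache = {}
        for y in range(first_year, end_year + 1):
            cyc = cycle_years[cycle_years <= y].max()
            if cyc not in cycle_cache:
                row = plot_bm.loc[cyc]
                cohorts = annual_litter(
                    row_to_components(row), species, turnover, awen,
                    mortality_fraction=float(row["mortality_frac"]),
                    harvested_share=float(row["harvest_share"]) / 5.0)
                cycle_cache[cyc] = cohorts_to_input(cohorts)
            L[i, y - start] = cycle_cache[cyc]
        # spin-up litter basis: first-inventory living + mortality, no harvest
        cohorts0 = annual_litter(
            row_to_components(first_row), species, turnover, awen,
            mortality_fraction=float(first_row["mortality_frac"]))
        first_inputs[i] = cohorts_to_input(cohorts0)
    return years, L, first_inputs


# ---------------------------------------------------------------------------
# the runner

def run_simulation(config: SimulationConfig, plots: pd.DataFrame,
                   climate: pd.DataFrame, biomass: pd.DataFrame,
                   params: ParameterSet | None = None,
                   turnover: TurnoverTable | None = None,
                   awen: AwenTable | None = None,
                   rules: RulesConfig | None = None) -> SimulationResult:
    """Run one simulation end to end; deterministic given its inputs."""
    params = params or default_parameters()
    turnover = turnover or TurnoverTable.default()
    awen = awen or AwenTable.default()
    rules = rules or RulesConfig()
    plots = plots.reset_index(drop=True)

    years, L, first_inputs = build_litter_series(
        plots, biomass, turnover, awen, rules, config.end_year)
    if climate["year"].min() > years[0] or climate["year"].max() < years[-1]:
        raise ValueError(
            f"climate series {climate['year'].min()}-{climate['year'].max()} "
            f"does not cover simulation span {years[0]}-{years[-1]}")

    # climate factors per plot-year under the scheme
    assigned = aggregation.aggregate_climate(plots, climate,
                                             config.spatial, config.temporal)
    assigned["factor"] = climate_modifier_vec(
        assigned["mat"].to_numpy(), assigned["t_min"].to_numpy(),
        assigned["t_max"].to_numpy(), assigned["precip_mm"].to_numpy(),
        params, config.use_sinusoid)
    fac = (assigned.pivot(index="plot_id", columns="year", values="factor")
           .reindex(plots["plot_id"])
           .reindex(columns=years))
    factors = fac.to_numpy()

    # spin-up: 1961-1990 normal at the simulation's spatial scale,
    # group-mean litter input
    normal = aggregation.spinup_normal(plots, climate, config.spatial) \
        .set_index("plot_id").reindex(plots["plot_id"])
    c_spin = climate_modifier_vec(
        normal["mat"].to_numpy(), normal["t_min"].to_numpy(),
        normal["t_max"].to_numpy(), normal["precip_mm"].to_numpy(),
        params, config.use_sinusoid)
    spin_inputs = group_mean_inputs(plots, first_inputs)
    n = len(plots)
    state = np.zeros((n, 3, 5))
    for i in range(n):
        state[i] = steady_state_pools(params, float(c_spin[i]), spin_inputs[i])
    initial_stock = pd.Series(state.sum(axis=(1, 2)),
                              index=plots["plot_id"], name="initial")

    # march the years
    props = [AnnualPropagator(params, size_modifier(d, params))
             for d in SIZE_CLASSES]
    start_years = plots["first_year"].to_numpy() - rules.presim_years
    stocks = np.full((n, years.size), np.nan)
    for t, year in enumerate(years):
        active = start_years <= year
        c = np.where(active, factors[:, t], 0.0)
        for s in range(3):
            b = np.where(active[:, None], L[:, t, s, :], 0.0)
            state[:, s, :] = props[s].step(c, state[:, s, :], b)
        stocks[active, t] = state[active].sum(axis=(1, 2))

    stocks_df = pd.DataFrame(stocks, index=pd.Index(plots["plot_id"],
                                                    name="plot_id"),
                             columns=years)
    return SimulationResult(config, years, plots, stocks_df, initial_stock)


def report(results: dict[str, SimulationResult],
           stock_period: tuple[int, int] = (2008, 2012),
           change_period: tuple[int, int] = (2000, 2012)) -> pd.DataFrame:
    """Tidy comparison table across completed simulations.

    One row per scope x unit x metric x simulation: country/district mean
    stocks over ``stock_period``, mean district stock change over
    ``change_period``, and national change (mean annual over
    ``change_period`` and cumulative over the full series) in Gg C.
    """
    rows = []
    for name, res in results.items():
        plots_idx = res.plots.set_index("plot_id")
        rows.append((name, "country", "all",
                     f"stock_mean_{stock_period[0]}_{stock_period[1]}",
                     res.mean_stock(stock_period)))
        for district, v in res.district_stock_means(stock_period).items():
            rows.append((name, "district", str(district),
                         f"stock_mean_{stock_period[0]}_{stock_period[1]}", v))
        change = res.stock_change(change_period)
        rows.append((name, "country", "all",
                     f"stock_change_{change_period[0]}_{change_period[1]}",
                     float(change.mean())))
        for district, v in change.groupby(plots_idx["district"]).mean().items():
            rows.append((name, "district", str(district),
                         f"stock_change_{change_period[0]}_{change_period[1]}", v))
        nat = res.national_change_gg()
        in_period = nat[(nat.index >= change_period[0])
                        & (nat.index <= change_period[1])]
        rows.append((name, "national", "all", "national_change_ggc_yr",
                     float(in_period.mean())))
        rows.append((name, "national", "all", "national_change_cum_gg",
                     res.cumulative_national_change_gg()))
    return pd.DataFrame(rows, columns=["simulation", "scope", "unit",
                                       "metric", "value"])
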
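"""Initial soil pools: steady-state spin-up and historical litter back-cast.

Every simulation starts each plot from a steady state obtained by running
the model for 5000 one-year steps under the 1961-1990 climate normal and a
constant litter input — the mean first-inventory litter of the plot's
(species x site-class) group. The plot then receives a deterministic
historical litter series for the ~30 pre-simulation years before its first
inventory, reconstructed from its attributes by rule class:

* ``mature`` (stand age > 34): biomass back-projected with the mean 5-year
  biomass-change rate, B(t-5) = B(t) / (1 + r);
* ``young_unproductive``: biomass held constant back in time;
* ``young_productive_continuous``: the previous rotation reconstructed to
  the recommended harvest age, with a harvest-residue pulse in the year the
  present stand was established;
* ``landuse_change``: a configured prior litter level before establishment;
* ``northern_lowprod``: stand development scaled back to age zero, then
  held constant (ground vegetation constant throughout).

After the pre-simulation the pools are deliberately *not* at steady state
whenever inputs or climate trend — that is the state the aggregation
experiment probes.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ClimateRecord, climate_modifier, size_modifier, steady_state
from .litter import (AwenTable, BiomassComponents, LitterCohort,
                     TurnoverTable, annual_litter, assign_awen,
                     cohorts_to_input, litter_from_mortality_and_harvest)
from .params import SIZE_CLASSES, ParameterSet, data_path
from .propagator import AnnualPropagator

__all__ = ["RulesConfig", "SpinUpDiagnostics", "spin_up", "steady_state_pools",
           "back_cast_litter", "group_mean_inputs"]

SPINUP_YEARS = 5000
SPINUP_TOL = 1e-6


def _default_harvest_ages() -> dict:
    frame = pd.read_csv(_io.StringIO(data_path("harvest_age.tsv").read_text()),
                        sep="\t", comment="#")
    return {(row.species, site): float(getattr(row, f"site_{site}"))
            for row in frame.itertuples() for site in (1, 2, 3)}


@dataclass(frozen=True)
class RulesConfig:
    """Parameters of the historical back-cast rules."""

    presim_years: int = 30
    #: mean per-5-year biomass change rate used to back-project mature stands
    mature_change_rate: float = 0.10
    #: annual natural-mortality fraction assumed during the pre-simulation
    presim_mortality: float = 0.003
    #: recommended harvest age by (species, site_class)
    harvest_ages: dict = field(default_factory=_default_harvest_ages)
    #: total biomass (kg C m^-2) of the reconstructed previous rotation at
    #: harvest age, by (species, site_class)
    rotation_biomass: dict = field(default_factory=lambda: {
        ("spruce", 1): 6.0, ("spruce", 2): 10.0, ("spruce", 3): 14.0,
        ("pine", 1): 5.0, ("pine", 2): 8.0, ("pine", 3): 11.0,
        ("deciduous", 1): 4.0, ("deciduous", 2): 6.0, ("deciduous", 3): 8.0,
    })
    #: component shares used to split rotation_biomass into components
    rotation_shares: dict = field(default_factory=lambda: {
        "stem": 0.42, "branches": 0.14, "stump": 0.05, "coarse_roots": 0.18,
        "foliage": 0.08})
    #: constant prior litter (kg C m^-2 yr^-1, non-woody) before a land-use change
    landuse_prior_litter: float = 0.15
    landuse_prior_chemistry: tuple = ("deciduous", "foliage")


# ---------------------------------------------------------------------------
# spin-up

@dataclass(frozen=True)
class SpinUpDiagnostics:
    last_step_rel_change: float
    converged: bool


def steady_state_pools(params: ParameterSet, climate_factor: float,
                       annual_input: np.ndarray) -> np.ndarray:
    """Analytic steady state per woody size class; (3, 5) pools array."""
    out = np.zeros((3, 5))
    for s, diameter in enumerate(SIZE_CLASSES):
        h = size_modifier(diameter, params)
        out[s] = steady_state(params, climate_factor, h, annual_input[s]).pools
    return out


def spin_up(params: ParameterSet, normal_climate: ClimateRecord,
            mean_input: np.ndarray, years: int = SPINUP_YEARS,
            use_sinusoid: bool = False,
            return_diagnostics: bool = False):
    """Pools after ``years`` annual steps under constant climate and input.

    ``mean_input`` is the (3 size classes, 5 pools) constant annual litter
    input. The recursion is evaluated in closed form (eigen coordinates of
    the annual step), which is exact for the iterated map; the convergence
    diagnostic measures the relative distance still separating the final
    state from the recursion's fixed point and warns when it exceeds 1e-6
    (the humus pool equilibrates slowly under low climate factors, so a
    5000-step spin-up is not always fully converged).
    """
    c = climate_modifier(normal_climate, params, use_sinusoid)
    pools = np.zeros((3, 5))
    worst = 0.0
    for s, diameter in enumerate(SIZE_CLASSES):
        prop = AnnualPropagator(params, size_modifier(diameter, params))
        carr = np.array([c])
        b = mean_input[s][None, :]
        x_end = prop.iterate(carr, np.zeros((1, 5)), b, years)
        x_inf = prop.fixed_point(carr, b)
        denom = np.maximum(np.abs(x_inf), 1e-300)
        worst = max(worst, float((np.abs(x_inf - x_end) / denom).max()))
        pools[s] = x_end[0]
    diag = SpinUpDiagnostics(worst, worst <= SPINUP_TOL)
    if not diag.converged:
        warnings.warn(
            f"spin-up not converged after {years} steps: "
            f"relative change {worst:.2e} > {SPINUP_TOL:g}", RuntimeWarning)
    if return_diagnostics:
        return pools, diag
    return pools


def group_mean_inputs(plots: pd.DataFrame, first_inputs: np.ndarray) -> np.ndarray:
    """Replace each plot's first-inventory litter input by the mean of its
    (species, site_class) group; ``first_inputs`` has shape (n_plots, 3, 5)."""
    out = np.empty_like(first_inputs)
    groups = plots.groupby(["species", "site_class"]).indices
    for _, idx in groups.items():
        out[idx] = first_inputs[idx].mean(axis=0)
    return out


# ---------------------------------------------------------------------------
# historical litter back-cast

def _rotation_components(species: str, site_class: int,
                         rules: RulesConfig) -> BiomassComponents:
    total = rules.rotation_biomass[(species, int(site_class))]
    sh = rules.rotation_shares
    foliage = sh["foliage"] * total
    return BiomassComponents(
        foliage=foliage, branches=sh["branches"] * total,
        stem=sh["stem"] * total, stump=sh["stump"] * total,
        coarse_roots=sh["coarse_roots"] * total,
        fine_roots=0.3 * foliage, ground_veg_above={})


def _scale_trees_only(b: BiomassComponents, factor: float) -> BiomassComponents:
    return BiomassComponents(
        foliage=b.foliage * factor, branches=b.branches * factor,
        stem=b.stem * factor, stump=b.stump * factor,
        coarse_roots=b.coarse_roots * factor, fine_roots=b.fine_roots * factor,
        ground_veg_above=dict(b.ground_veg_above),
        ground_veg_below=dict(b.ground_veg_below))


def back_cast_litter(plot: pd.Series, first_biomass: BiomassComponents,
                     rules: RulesConfig, turnover: TurnoverTable,
                     awen: AwenTable) -> dict[int, list[LitterCohort]]:
    """Deterministic annual litter cohorts for the pre-simulation years.

    Pure function of (plot attributes, first-inventory biomass, rules):
    returns {year: cohorts} for the ``presim_years`` years before the
    plot's first inventory year.
    """
    history = plot["history"]
    first_year = int(plot["first_year"])
    species = plot["species"]
    site = int(plot["site_class"])
    age0 = int(plot["age"])
    years = range(first_year - rules.presim_years, first_year)

    out: dict[int, list[LitterCohort]] = {}
    birth_year = first_year - age0
    cache: dict[int, list[LitterCohort]] = {}
    for year in years:
        back = first_year - year               # years before first inventory
        blocks_back = (back + 4) // 5          # 5-year cycles before it
        pulse: list[LitterCohort] = []
        if history == "mature":
            factor = (1.0 + rules.mature_change_rate) ** (-blocks_back)
            biomass = first_biomass.scaled(factor)
        elif history == "young_unproductive":
            biomass = first_biomass
        elif history == "northern_lowprod":
            age_then = age0 - 5 * blocks_back
            factor = min(1.0, max(age_then, 0) / max(age0, 1))
            biomass = _scale_trees_only(first_biomass, factor)
        elif history in ("young_productive_continuous", "landuse_change"):
            if year >= birth_year:
                age_then = max(age0 - 5 * blocks_back, 0)
                factor = min(1.0, age_then / max(age0, 1))
                biomass = _scale_trees_only(first_biomass, factor)
                if history == "young_productive_continuous" and year == birth_year:
                    prev = _rotation_components(species, site, rules)
                    residue = litter_from_mortality_and_harvest(
                        prev, species, harvested_share=1.0)
                    pulse = [assign_awen(c, c.species, c.component, awen)
                             for c in residue]
            else:
                if history == "landuse_change":
                    sp, comp = rules.landuse_prior_chemistry
                    prior = LitterCohort(rules.landuse_prior_litter, 0.0,
                                         species=sp, component=comp)
                    out[year] = [assign_awen(prior, sp, comp, awen)]
                    continue
                # previous rotation, held at its harvest-age biomass
                biomass = _rotation_components(species, site, rules)
        else:
            raise ValueError(
                f"plot {plot['plot_id']}: unclassifiable history {history!r} "
                f"(age={age0}, site={site}, species={species})")
        if not pulse and blocks_back in cache:
            out[year] = cache[blocks_back]
            continue
        cohorts = annual_litter(biomass, species, turnover, awen,
                                mortality_fraction=rules.presim_mortality)
        cache[blocks_back] = cohorts
        out[year] = cohorts + pulse
    return out


def back_cast_inputs(plot: pd.Series, first_biomass: BiomassComponents,
                     rules: RulesConfig, turnover: TurnoverTable,
                     awen: AwenTable) -> tuple[np.ndarray, np.ndarray]:
    """Back-cast litter as (years, (n_years, 3, 5)) input arrays."""
    series = back_cast_litter(plot, first_biomass, rules, turnover, awen)
    years = np.array(sorted(series))
    arr = np.stack([cohorts_to_input(series[y]) for y in years])
    return years, arr
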
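"""Synthetic inventory landscapes: plots, climate series and biomass.

The generator emulates the structure of a northern national forest
inventory so the whole pipeline runs without any confidential data:

* a plot network grouped into districts and three climatic regions — a
  warm-wet coastal southwest, a colder and drier southeast, and a cold
  north — each plot representing ~900 ha;
* per-plot climate series (1956-2012 by default) with regional baselines,
  a linear post-1990 warming/wetting trend and independent interannual
  noise;
* species- and age-structured biomass re-measured on a 5-year inventory
  cycle, with logistic age-biomass curves, occasional clear-cut harvests
  and a small natural-mortality fraction.

Regional baseline values are plausible defaults for the emulated gradient,
not values taken from any measured data set. All three streams are seeded
independently from one integer seed and are fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .litter import FINE_ROOT_TO_FOLIAGE

__all__ = ["GeneratorConfig", "generate_landscape", "generate_climate",
           "generate_biomass", "generate_dataset", "biomass_curve",
           "BIOMASS_COLUMNS"]

REGIONS = ("southeast", "southwest", "north")

BIOMASS_COLUMNS = [
    "plot_id", "year", "foliage", "branches", "stem", "stump",
    "coarse_roots", "fine_roots", "gv_moss", "gv_lichen",
    "gv_herbs_grasses", "gv_dwarf_shrubs", "mortality_frac", "harvest_share",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Defaults defining the emulated study conditions."""

    # region -> (mean annual temperature degC, annual precipitation mm,
    #            seasonal half-amplitude degC)
    region_climate: dict = field(default_factory=lambda: {
        "southwest": (6.0, 2000.0, 7.0),
        "southeast": (3.0, 700.0, 10.0),
        "north": (0.0, 600.0, 12.0),
    })
    region_shares: dict = field(default_factory=lambda: {
        "southeast": 0.45, "southwest": 0.25, "north": 0.30})
    # species mix per region (spruce, pine, deciduous)
    species_mix: dict = field(default_factory=lambda: {
        "southeast": (0.50, 0.35, 0.15),
        "southwest": (0.35, 0.30, 0.35),
        "north": (0.20, 0.30, 0.50),
    })
    # site productivity class probabilities (class 1 low .. 3 high)
    site_probs: dict = field(default_factory=lambda: {
        "southeast": (0.25, 0.45, 0.30),
        "southwest": (0.25, 0.45, 0.30),
        "north": (0.55, 0.35, 0.10),
    })
    area_ha: float = 900.0
    age_mean: float = 70.0
    age_sd: float = 35.0
    org_layer_log_mean: float = -2.12   # ln metres; ~7% of plots >= 0.4 m
    org_layer_log_sd: float = 0.8
    # climate trend (post-1990) and interannual noise
    trend_t: float = 0.04        # degC yr^-1
    trend_p: float = 3.0         # mm yr^-1
    trend_start: int = 1990
    district_sd_t: float = 0.5
    district_sd_p_frac: float = 0.07
    plot_sd_t: float = 0.8
    plot_sd_p_frac: float = 0.12
    noise_sd_t: float = 0.7
    noise_sd_p_frac: float = 0.10
    # biomass model: species -> (max total kg C m^-2, age at half max, slope yr)
    biomass_max: dict = field(default_factory=lambda: {
        "spruce": 9.0, "pine": 7.0, "deciduous": 5.0})
    biomass_a50: dict = field(default_factory=lambda: {
        "spruce": 45.0, "pine": 40.0, "deciduous": 30.0})
    biomass_slope: dict = field(default_factory=lambda: {
        "spruce": 15.0, "pine": 15.0, "deciduous": 12.0})
    site_factor: dict = field(default_factory=lambda: {1: 0.6, 2: 1.0, 3: 1.4})
    # component shares of total stand biomass
    shares: dict = field(default_factory=lambda: {
        "stem": 0.42, "branches": 0.14, "stump": 0.05, "coarse_roots": 0.18})
    foliage_share: dict = field(default_factory=lambda: {
        "spruce": 0.075, "pine": 0.033, "deciduous": 0.025})
    plot_productivity_sd: float = 0.2   # lognormal sd of per-plot multiplier
    # ground vegetation above-ground totals per region, kg C m^-2
    gv_total: dict = field(default_factory=lambda: {
        "southeast": 0.08, "southwest": 0.10, "north": 0.13})
    gv_split: dict = field(default_factory=lambda: {
        "southeast": (0.50, 0.05, 0.20, 0.25),
        "southwest": (0.50, 0.05, 0.25, 0.20),
        "north": (0.40, 0.20, 0.10, 0.30),
    })  # moss, lichen, herbs_grasses, dwarf_shrubs
    mortality_lo: float = 0.002  # annual fraction
    mortality_hi: float = 0.006
    harvest_prob: float = 0.15   # per cycle once past harvest age
    harvest_age: dict = field(default_factory=lambda: {
        "spruce": 100.0, "pine": 110.0, "deciduous": 70.0})
    first_inventory_years: tuple = (1986, 1990)
    last_year: int = 2012


def _streams(seed: int, n: int = 3):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_landscape(n_plots: int, n_districts: int = 19, seed: int = 0,
                       config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Plot table: identity, district/region membership and attributes."""
    cfg = config or GeneratorConfig()
    if not n_plots >= n_districts >= len(REGIONS):
        raise ValueError("need n_plots >= n_districts >= number of regions")
    rng = _streams(seed)[0]

    # districts partitioned over regions proportionally to region shares
    shares = np.array([cfg.region_shares[r] for r in REGIONS])
    counts = np.maximum(1, np.round(shares / shares.sum() * n_districts).astype(int))
    while counts.sum() > n_districts:
        counts[np.argmax(counts)] -= 1
    while counts.sum() < n_districts:
        counts[np.argmin(counts)] += 1
    district_region = np.repeat(REGIONS, counts)[:n_districts]

    district = rng.integers(0, n_districts, size=n_plots)
    # guarantee every district is populated when possible
    district[:n_districts] = np.arange(n_districts)
    region = district_region[district]

    species = np.empty(n_plots, dtype=object)
    site = np.empty(n_plots, dtype=int)
    for r in REGIONS:
        mask = region == r
        species[mask] = rng.choice(["spruce", "pine", "deciduous"],
                                   size=mask.sum(), p=cfg.species_mix[r])
        site[mask] = rng.choice([1, 2, 3], size=mask.sum(), p=cfg.site_probs[r])

    age = np.clip(rng.normal(cfg.age_mean, cfg.age_sd, n_plots), 5, 200).astype(int)
    org = np.exp(rng.normal(cfg.org_layer_log_mean, cfg.org_layer_log_sd, n_plots))
    y0, y1 = cfg.first_inventory_years
    first_year = y0 + rng.integers(0, y1 - y0 + 1, size=n_plots)

    history = np.empty(n_plots, dtype=object)
    for i in range(n_plots):
        if region[i] == "north" and site[i] == 1:
            history[i] = "northern_lowprod"
        elif age[i] > 34:
            history[i] = "mature"
        elif site[i] == 1:
            history[i] = "young_unproductive"
        else:
            history[i] = ("young_productive_continuous"
                          if rng.random() < 0.9 else "landuse_change")

    return pd.DataFrame({
        "plot_id": np.arange(n_plots), "district": district, "region": region,
        "area_ha": cfg.area_ha, "species": species, "site_class": site,
        "age": age, "org_layer_m": np.round(org, 3), "first_year": first_year,
        "history": history,
    })


def generate_climate(plots: pd.DataFrame, years: tuple[int, int] = (1956, 2012),
                     seed: int = 0,
                     config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Per plot-year climate with regional baselines, trend and noise."""
    cfg = config or GeneratorConfig()
    rng = _streams(seed)[1]
    year = np.arange(years[0], years[1] + 1)
    n_years = year.size
    n_plots = len(plots)

    districts = np.sort(plots["district"].unique())
    d_t = rng.normal(0.0, cfg.district_sd_t, districts.size)
    d_p = rng.normal(0.0, cfg.district_sd_p_frac, districts.size)
    d_index = {d: i for i, d in enumerate(districts)}

    base_t = np.empty(n_plots)
    base_p = np.empty(n_plots)
    amp = np.empty(n_plots)
    for i, row in enumerate(plots.itertuples()):
        t0, p0, a0 = cfg.region_climate[row.region]
        j = d_index[row.district]
        base_t[i] = t0 + d_t[j] + rng.normal(0.0, cfg.plot_sd_t)
        base_p[i] = p0 * (1.0 + d_p[j] + rng.normal(0.0, cfg.plot_sd_p_frac))
        amp[i] = max(2.0, a0 + rng.normal(0.0, 1.0))

    trend_years = np.maximum(0, year - cfg.trend_start)          # (n_years,)
    mat = (base_t[:, None] + cfg.trend_t * trend_years[None, :]
           + rng.normal(0.0, cfg.noise_sd_t, (n_plots, n_years)))
    precip = (base_p[:, None] + cfg.trend_p * trend_years[None, :]) \
        * np.exp(rng.normal(0.0, cfg.noise_sd_p_frac, (n_plots, n_years)))
    precip = np.maximum(precip, 0.0)

    out = pd.DataFrame({
        "plot_id": np.repeat(plots["plot_id"].to_numpy(), n_years),
        "year": np.tile(year, n_plots),
        "mat": mat.ravel(),
        "t_min": (mat - amp[:, None]).ravel(),
        "t_max": (mat + amp[:, None]).ravel(),
        "precip_mm": precip.ravel(),
    })
    return out


def biomass_curve(age, species: str, site_class: int,
                  config: GeneratorConfig | None = None):
    """Logistic total stand biomass (kg C m^-2) at a given age."""
    cfg = config or GeneratorConfig()
    age = np.asarray(age, dtype=float)
    bmax = cfg.biomass_max[species] * cfg.site_factor[int(site_class)]
    a50 = cfg.biomass_a50[species]
    s = cfg.biomass_slope[species]
    raw = bmax / (1.0 + np.exp(-(age - a50) / s))
    # anchor to ~0 at age 0 so young stands are near-bare
    raw0 = bmax / (1.0 + np.exp(a50 / s))
    return np.maximum(raw - raw0, 0.0)


def _components(total: float, species: str, gv_above: np.ndarray,
                cfg: GeneratorConfig) -> dict:
    fol = cfg.foliage_share[species] * total
    return {
        "foliage": fol,
        "branches": cfg.shares["branches"] * total,
        "stem": cfg.shares["stem"] * total,
        "stump": cfg.shares["stump"] * total,
        "coarse_roots": cfg.shares["coarse_roots"] * total,
        "fine_roots": FINE_ROOT_TO_FOLIAGE * fol,
        "gv_moss": gv_above[0], "gv_lichen": gv_above[1],
        "gv_herbs_grasses": gv_above[2], "gv_dwarf_shrubs": gv_above[3],
    }


def generate_biomass(plots: pd.DataFrame, seed: int = 0,
                     config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Per-cycle biomass components, mortality and harvest events.

    One row per plot and 5-year inventory cycle from the plot's first
    inventory year to the end of the series. ``harvest_share`` is the share
    of the standing biomass clear-cut during that cycle (stem extracted,
    residues to litter); after a harvest the stand age restarts.
    """
    cfg = config or GeneratorConfig()
    rng = _streams(seed)[2]
    rows = []
    for row in plots.itertuples():
        mult = float(np.exp(rng.normal(0.0, cfg.plot_productivity_sd)))
        gv = cfg.gv_total[row.region] * np.array(cfg.gv_split[row.region])
        age = float(row.age)
        for year in range(int(row.first_year), cfg.last_year + 1, 5):
            total = float(biomass_curve(age, row.species, row.site_class, cfg)) * mult
            mortality = float(rng.uniform(cfg.mortality_lo, cfg.mortality_hi))
            harvest = 0.0
            if age >= cfg.harvest_age[row.species] and rng.random() < cfg.harvest_prob:
                harvest = 1.0
            comps = _components(total, row.species, gv, cfg)
            rows.append({"plot_id": row.plot_id, "year": year,
                         **comps, "mortality_frac": mortality,
                         "harvest_share": harvest})
            age = 5.0 if harvest else age + 5.0
    return pd.DataFrame(rows, columns=BIOMASS_COLUMNS)


def generate_dataset(n_plots: int, seed: int = 0, n_districts: int = 19,
                     years: tuple[int, int] = (1956, 2012),
                     config: GeneratorConfig | None = None):
    """Convenience: (plots, climate, biomass) from one seed."""
    cfg = config or GeneratorConfig()
    plots = generate_landscape(n_plots, n_districts, seed, cfg)
    climate = generate_climate(plots, years, seed, cfg)
    biomass = generate_biomass(plots, seed, cfg)
    return plots, climate, biomass
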
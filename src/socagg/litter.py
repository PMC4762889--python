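"""Litter input: from plot biomass to chemically partitioned annual cohorts.

Living vegetation sheds carbon at component-specific annual turnover rates
(foliage, branches + coarse roots, fine roots for trees; above/below ground
for four ground-vegetation classes). Natural mortality and harvest transfer
whole-tree components at once; commercially harvested stems leave the
system, everything else (stumps, branches, foliage, roots) stays as
residue. Each resulting cohort carries a chemical partition over the four
labile pools (A, W, E, N) and a woody size class: 0 cm for non-woody
litter, 2 cm for branches and coarse roots, 10 cm for stems and stumps.

Two ratio rules close gaps in inventory data: fine-root biomass is
0.3 x foliage biomass, and below-ground ground-vegetation biomass is twice
the above-ground amount.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .params import data_path

__all__ = [
    "GV_CLASSES", "TREE_COMPONENTS", "SPECIES", "SIZE_INDEX",
    "BiomassComponents", "LitterCohort", "TurnoverTable", "AwenTable",
    "derive_fine_roots", "derive_ground_veg_below", "litter_from_living",
    "litter_from_mortality_and_harvest", "assign_awen", "annual_litter",
    "cohorts_to_input", "total_litter_mass",
]

SPECIES = ("spruce", "pine", "deciduous")
TREE_COMPONENTS = ("foliage", "branches", "stem", "stump",
                   "coarse_roots", "fine_roots")
GV_CLASSES = ("moss", "lichen", "herbs_grasses", "dwarf_shrubs")

FINE_ROOT_TO_FOLIAGE = 0.3
GV_BELOW_TO_ABOVE = 2.0

#: size class (cm) per tree component
COMPONENT_SIZE = {
    "foliage": 0.0, "fine_roots": 0.0,
    "branches": 2.0, "coarse_roots": 2.0,
    "stem": 10.0, "stump": 10.0,
}
SIZE_INDEX = {0.0: 0, 2.0: 1, 10.0: 2}


def derive_fine_roots(foliage_biomass: float) -> float:
    """Fine-root biomass (< 2 mm) from foliage biomass: 0.3 x foliage."""
    if foliage_biomass < 0:
        raise ValueError("negative foliage biomass")
    return FINE_ROOT_TO_FOLIAGE * foliage_biomass


def derive_ground_veg_below(above_biomass: float) -> float:
    """Below-ground ground-vegetation biomass: twice the above-ground."""
    if above_biomass < 0:
        raise ValueError("negative above-ground biomass")
    return GV_BELOW_TO_ABOVE * above_biomass


@dataclass(frozen=True)
class BiomassComponents:
    """Standing biomass of one plot, kg C m^-2 per component.

    ``ground_veg_above`` maps ground-vegetation class -> above-ground mass;
    the below-ground masses default to the 2x rule when not given.
    """

    foliage: float = 0.0
    branches: float = 0.0          # live and dead branches
    stem: float = 0.0
    stump: float = 0.0
    coarse_roots: float = 0.0      # roots > 2 mm
    fine_roots: float = 0.0        # roots < 2 mm
    ground_veg_above: dict = field(default_factory=dict)
    ground_veg_below: dict | None = None

    def __post_init__(self) -> None:
        vals = [self.foliage, self.branches, self.stem, self.stump,
                self.coarse_roots, self.fine_roots,
                *self.ground_veg_above.values(),
                *(self.ground_veg_below or {}).values()]
        if any(v < 0 for v in vals):
            raise ValueError("biomass components must be >= 0")
        if self.ground_veg_below is None:
            below = {c: derive_ground_veg_below(m)
                     for c, m in self.ground_veg_above.items()}
            object.__setattr__(self, "ground_veg_below", below)

    def scaled(self, factor: float) -> "BiomassComponents":
        return BiomassComponents(
            foliage=self.foliage * factor, branches=self.branches * factor,
            stem=self.stem * factor, stump=self.stump * factor,
            coarse_roots=self.coarse_roots * factor,
            fine_roots=self.fine_roots * factor,
            ground_veg_above={c: m * factor
                              for c, m in self.ground_veg_above.items()},
            ground_veg_below={c: m * factor
                              for c, m in self.ground_veg_below.items()},
        )


@dataclass(frozen=True)
class LitterCohort:
    """An annual litter mass with chemical partition and woody size class."""

    mass: float                      # kg C m^-2 yr^-1
    size_class: float                # cm, one of 0, 2, 10
    awen_fractions: np.ndarray | None = None
    species: str | None = None       # provenance for chemistry lookup
    component: str | None = None

    def __post_init__(self) -> None:
        if self.mass < 0:
            raise ValueError("negative cohort mass")
        if self.size_class not in SIZE_INDEX:
            raise ValueError(f"unknown size class {self.size_class} cm")
        if self.awen_fractions is not None:
            f = np.asarray(self.awen_fractions, dtype=float)
            if f.shape != (4,) or np.any(f < 0) or abs(f.sum() - 1) > 1e-9:
                raise ValueError("awen_fractions must be >= 0 and sum to 1")
            object.__setattr__(self, "awen_fractions", f)


# ---------------------------------------------------------------------------
# tables

class TurnoverTable:
    """Annual turnover rates per species x tree component and per
    ground-vegetation class x layer. Missing ground-vegetation below-ground
    rates (moss, lichen) mean that layer produces no litter."""

    def __init__(self, trees: pd.DataFrame, groundveg: pd.DataFrame):
        self.trees = trees.set_index("component") if "component" in trees else trees
        self.groundveg = groundveg.set_index("layer") if "layer" in groundveg else groundveg
        rates = self.trees.to_numpy(dtype=float)
        if np.any((rates <= 0) | (rates > 1)):
            raise ValueError("tree turnover rates must be in (0, 1]")

    @classmethod
    def default(cls) -> "TurnoverTable":
        trees = pd.read_csv(_io.StringIO(data_path("turnover_trees.tsv").read_text()),
                            sep="\t", comment="#")
        gv = pd.read_csv(_io.StringIO(data_path("turnover_groundveg.tsv").read_text()),
                         sep="\t", comment="#")
        return cls(trees, gv)

    def tree_rate(self, species: str, component: str) -> float:
        if species not in self.trees.columns:
            raise KeyError(f"unknown species {species!r}")
        return float(self.trees.loc[component, species])

    def gv_rate(self, layer: str, gv_class: str) -> float | None:
        v = self.groundveg.loc[layer, gv_class]
        return None if pd.isna(v) else float(v)


class AwenTable:
    """Chemical partition (A, W, E, N fractions) per species x component."""

    def __init__(self, frame: pd.DataFrame):
        frame = frame.set_index(["species", "component"])
        sums = frame[["a", "w", "e", "n"]].sum(axis=1)
        if np.any(np.abs(sums - 1) > 1e-9) or (frame[["a", "w", "e", "n"]] < 0).any().any():
            raise ValueError("each chemistry row must be a simplex over A,W,E,N")
        self.frame = frame
        self._map = {key: row[["a", "w", "e", "n"]].to_numpy(dtype=float)
                     for key, row in frame.iterrows()}

    @classmethod
    def default(cls) -> "AwenTable":
        frame = pd.read_csv(_io.StringIO(data_path("awen_chemistry.tsv").read_text()),
                            sep="\t", comment="#")
        return cls(frame)

    def fractions(self, species: str, component: str) -> np.ndarray:
        try:
            return self._map[(species, component)]
        except KeyError:
            raise KeyError(
                f"no chemistry row for species={species!r}, component={component!r}"
            ) from None


# ---------------------------------------------------------------------------
# operations

def litter_from_living(biomass: BiomassComponents, species: str,
                       turnover: TurnoverTable) -> list[LitterCohort]:
    """Annual litter shed by living vegetation: biomass x turnover rate.

    Stems and stumps of living trees shed nothing here — they enter the
    litter pool only through mortality and harvest.
    """
    if species not in SPECIES:
        raise ValueError(f"unknown species {species!r}")
    cohorts = []
    for comp in ("foliage", "branches", "coarse_roots", "fine_roots"):
        mass = getattr(biomass, comp) * turnover.tree_rate(species, comp)
        cohorts.append(LitterCohort(mass, COMPONENT_SIZE[comp],
                                    species=species, component=comp))
    for layer, pools in (("above", biomass.ground_veg_above),
                         ("below", biomass.ground_veg_below)):
        for gv_class, mass in pools.items():
            rate = turnover.gv_rate(layer, gv_class)
            if rate is None:
                continue
            cohorts.append(LitterCohort(mass * rate, 0.0,
                                        species="groundveg", component=gv_class))
    return cohorts


def litter_from_mortality_and_harvest(
        biomass: BiomassComponents, species: str,
        mortality_fraction: float = 0.0,
        harvested_share: float = 0.0) -> list[LitterCohort]:
    """Litter transfer from dying and harvested trees.

    The dying share moves every tree component to litter in its size class.
    The harvested share leaves its residues (stump, branches, foliage,
    coarse and fine roots) as litter; stems are extracted commercially and
    leave the system.
    """
    for name, frac in (("mortality_fraction", mortality_fraction),
                       ("harvested_share", harvested_share)):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {frac}")
    cohorts = []
    if mortality_fraction > 0:
        for comp in TREE_COMPONENTS:
            mass = getattr(biomass, comp) * mortality_fraction
            cohorts.append(LitterCohort(mass, COMPONENT_SIZE[comp],
                                        species=species, component=comp))
    if harvested_share > 0:
        for comp in TREE_COMPONENTS:
            if comp == "stem":
                continue  # removed as product
            mass = getattr(biomass, comp) * harvested_share
            cohorts.append(LitterCohort(mass, COMPONENT_SIZE[comp],
                                        species=species, component=comp))
    return cohorts


def assign_awen(cohort: LitterCohort, species: str, component: str,
                awen_table: AwenTable) -> LitterCohort:
    """Attach the chemical partition of (species, component) to a cohort."""
    fractions = awen_table.fractions(species, component)
    return replace(cohort, awen_fractions=fractions,
                   species=species, component=component)


def annual_litter(biomass: BiomassComponents, species: str,
                  turnover: TurnoverTable, awen_table: AwenTable,
                  mortality_fraction: float = 0.0,
                  harvested_share: float = 0.0) -> list[LitterCohort]:
    """All litter cohorts of one plot-year, chemistry attached."""
    cohorts = litter_from_living(biomass, species, turnover)
    cohorts += litter_from_mortality_and_harvest(
        biomass, species, mortality_fraction, harvested_share)
    return [assign_awen(c, c.species, c.component, awen_table)
            for c in cohorts]


def cohorts_to_input(cohorts: list[LitterCohort]) -> np.ndarray:
    """Stack cohorts into a (3 size classes, 5 pools) annual input array.

    Litter enters the four labile pools according to its chemical partition;
    the humus column receives no direct input.
    """
    out = np.zeros((3, 5))
    for c in cohorts:
        if c.awen_fractions is None:
            raise ValueError("cohort lacks a chemical partition; run assign_awen")
        out[SIZE_INDEX[c.size_class], :4] += c.mass * c.awen_fractions
    return out


def total_litter_mass(cohorts: list[LitterCohort]) -> float:
    return float(sum(c.mass for c in cohorts))
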
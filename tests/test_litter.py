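"""Litter bookkeeping: turnover rates, ratio rules, cohorts, chemistry."""

import numpy as np
import pandas as pd
import pytest

from socagg.litter import (AwenTable, BiomassComponents, LitterCohort,
                           TurnoverTable, annual_litter, assign_awen,
                           cohorts_to_input, derive_fine_roots,
                           derive_ground_veg_below, litter_from_living,
                           litter_from_mortality_and_harvest,
                           total_litter_mass)


def stand(foliage=1.0, branches=0.0, stem=0.0, stump=0.0, coarse=0.0,
          gv=None):
    return BiomassComponents(
        foliage=foliage, branches=branches, stem=stem, stump=stump,
        coarse_roots=coarse, fine_roots=derive_fine_roots(foliage),
        ground_veg_above=gv or {})


# ---------------------------------------------------------------------------
# ratio rules

@pytest.mark.parametrize("foliage,expected", [(1.0, 0.3), (0.0, 0.0),
                                              (0.42, 0.126)])
def test_fine_root_rule(foliage, expected):
    assert derive_fine_roots(foliage) == pytest.approx(expected)


@pytest.mark.parametrize("above,expected", [(0.1, 0.2), (0.0, 0.0),
                                            (0.35, 0.70)])
def test_ground_veg_below_rule(above, expected):
    assert derive_ground_veg_below(above) == pytest.approx(expected)


def test_negative_biomass_rejected():
    with pytest.raises(ValueError):
        derive_fine_roots(-1.0)
    with pytest.raises(ValueError):
        BiomassComponents(foliage=-0.1)


# ---------------------------------------------------------------------------
# living litter

class TestLitterFromLiving:
    def test_spruce_foliage_rate(self, turnover):
        cohorts = litter_from_living(stand(foliage=1.0), "spruce", turnover)
        fol = next(c for c in cohorts if c.component == "foliage")
        assert fol.mass == pytest.approx(0.143)
        assert fol.size_class == 0.0

    def test_deciduous_foliage_full_annual_shed(self, turnover):
        cohorts = litter_from_living(stand(foliage=1.0), "deciduous", turnover)
        fol = next(c for c in cohorts if c.component == "foliage")
        assert fol.mass == pytest.approx(1.0)

    def test_pine_branches(self, turnover):
        cohorts = litter_from_living(stand(foliage=0.0, branches=2.0),
                                     "pine", turnover)
        br = next(c for c in cohorts if c.component == "branches")
        assert br.mass == pytest.approx(0.054)
        assert br.size_class == 2.0

    def test_living_stems_and_stumps_shed_nothing(self, turnover):
        cohorts = litter_from_living(stand(stem=5.0, stump=1.0),
                                     "spruce", turnover)
        assert all(c.component not in ("stem", "stump") for c in cohorts)

    def test_table_faithful_branch_ordering(self, turnover):
        """Pine branch turnover (0.027) exceeds spruce (0.0125)."""
        b = stand(foliage=0.0, branches=1.0)
        pine = total_litter_mass([c for c in litter_from_living(b, "pine", turnover)
                                  if c.component == "branches"])
        spruce = total_litter_mass([c for c in litter_from_living(b, "spruce", turnover)
                                    if c.component == "branches"])
        assert pine > spruce

    def test_moss_and_lichen_have_no_belowground_litter(self, turnover):
        b = BiomassComponents(ground_veg_above={"moss": 1.0, "lichen": 1.0,
                                                "herbs_grasses": 1.0,
                                                "dwarf_shrubs": 0.0})
        cohorts = litter_from_living(b, "spruce", turnover)
        gv = [c.component for c in cohorts if c.species == "groundveg"]
        # above: all four classes present (shrubs with zero mass), below: herbs only
        assert gv.count("herbs_grasses") == 2
        assert gv.count("moss") == 1 and gv.count("lichen") == 1

    def test_unknown_species_fails(self, turnover):
        with pytest.raises(ValueError):
            litter_from_living(stand(), "larch", turnover)


# ---------------------------------------------------------------------------
# mortality and harvest

class TestMortalityHarvest:
    def test_zero_mortality_empty(self):
        assert litter_from_mortality_and_harvest(stand(), "pine") == []

    def test_full_mortality_transfers_stem_at_coarse_size(self):
        b = stand(foliage=0.0, stem=1.0)
        cohorts = litter_from_mortality_and_harvest(b, "pine",
                                                    mortality_fraction=1.0)
        stemc = next(c for c in cohorts if c.component == "stem")
        assert stemc.mass == pytest.approx(1.0)
        assert stemc.size_class == 10.0

    def test_harvest_residue_bookkeeping(self):
        """Residue mass = all components minus the extracted stems."""
        b = BiomassComponents(foliage=0.8, branches=1.1, stem=4.2, stump=0.5,
                              coarse_roots=1.4, fine_roots=0.24,
                              ground_veg_above={})
        share = 0.6
        cohorts = litter_from_mortality_and_harvest(b, "spruce",
                                                    harvested_share=share)
        total = total_litter_mass(cohorts)
        component_sum = (b.foliage + b.branches + b.stump + b.coarse_roots
                         + b.fine_roots) * share  # brute-force oracle
        assert total == pytest.approx(component_sum, rel=1e-12)
        assert all(c.component != "stem" for c in cohorts)

    def test_fraction_above_one_fails(self):
        with pytest.raises(ValueError):
            litter_from_mortality_and_harvest(stand(), "pine",
                                              mortality_fraction=1.2)


# ---------------------------------------------------------------------------
# chemistry

class TestChemistry:
    def test_fractions_attach_and_sum_to_one(self, awen):
        c = assign_awen(LitterCohort(0.5, 0.0), "spruce", "foliage", awen)
        assert c.awen_fractions.sum() == pytest.approx(1.0)

    def test_missing_row_names_the_lookup(self, awen):
        with pytest.raises(KeyError, match="larch.*cones"):
            assign_awen(LitterCohort(0.5, 0.0), "larch", "cones", awen)

    def test_swapping_table_rows_changes_output(self, awen):
        frame = awen.frame.reset_index()
        swapped = frame.copy()
        i = frame.index[(frame.species == "spruce") & (frame.component == "foliage")][0]
        j = frame.index[(frame.species == "pine") & (frame.component == "stem")][0]
        cols = ["a", "w", "e", "n"]
        swapped.loc[i, cols], swapped.loc[j, cols] = \
            frame.loc[j, cols].to_numpy(), frame.loc[i, cols].to_numpy()
        other = AwenTable(swapped)
        a = assign_awen(LitterCohort(1.0, 0.0), "spruce", "foliage", awen)
        b = assign_awen(LitterCohort(1.0, 0.0), "spruce", "foliage", other)
        assert not np.allclose(a.awen_fractions, b.awen_fractions)

    def test_non_simplex_table_rejected(self):
        bad = pd.DataFrame({"species": ["x"], "component": ["y"],
                            "a": [0.5], "w": [0.5], "e": [0.5], "n": [0.5]})
        with pytest.raises(ValueError):
            AwenTable(bad)

    def test_default_table_rows_are_simplices(self, awen):
        sums = awen.frame[["a", "w", "e", "n"]].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)


# ---------------------------------------------------------------------------
# conservation

class TestConservation:
    def test_plot_year_litter_conservation(self, turnover, awen):
        """Total litter C = sum(biomass x turnover) + transfer terms, exactly."""
        b = BiomassComponents(foliage=0.9, branches=1.2, stem=3.8, stump=0.4,
                              coarse_roots=1.1, fine_roots=0.27,
                              ground_veg_above={"moss": 0.2, "lichen": 0.05,
                                                "herbs_grasses": 0.1,
                                                "dwarf_shrubs": 0.15})
        mort, harv = 0.013, 0.08
        cohorts = annual_litter(b, "pine", turnover, awen,
                                mortality_fraction=mort, harvested_share=harv)
        # independent bookkeeping oracle
        expected = 0.0
        for comp in ("foliage", "branches", "coarse_roots", "fine_roots"):
            expected += getattr(b, comp) * turnover.tree_rate("pine", comp)
        for cls, above in b.ground_veg_above.items():
            expected += above * (turnover.gv_rate("above", cls) or 0.0)
        for cls, below in b.ground_veg_below.items():
            expected += below * (turnover.gv_rate("below", cls) or 0.0)
        tree_total = (b.foliage + b.branches + b.stem + b.stump
                      + b.coarse_roots + b.fine_roots)
        expected += mort * tree_total
        expected += harv * (tree_total - b.stem)
        assert total_litter_mass(cohorts) == pytest.approx(expected, rel=1e-12)

    def test_cohort_array_conserves_mass(self, turnover, awen):
        """The (size, pool) input array holds exactly the cohort carbon."""
        b = stand(foliage=1.3, branches=0.8, coarse=0.6,
                  gv={"moss": 0.2, "herbs_grasses": 0.1,
                      "lichen": 0.0, "dwarf_shrubs": 0.05})
        cohorts = annual_litter(b, "spruce", turnover, awen,
                                mortality_fraction=0.01)
        arr = cohorts_to_input(cohorts)
        assert arr[:, 4].sum() == 0.0  # no direct humus input
        assert arr.sum() == pytest.approx(total_litter_mass(cohorts), rel=1e-12)

    def test_unassigned_cohort_rejected_by_array_builder(self):
        with pytest.raises(ValueError):
            cohorts_to_input([LitterCohort(1.0, 0.0)])
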
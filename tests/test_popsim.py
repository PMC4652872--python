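"""Meiosis, bioassay and family-simulation behaviour of the forward simulator."""

import numpy as np
import pytest

from lepilink import popsim
from lepilink.popsim import (
    CODOMINANT,
    DOMINANT,
    FamilyDesign,
    MarkerDef,
    RecombMap,
    TraitLocus,
    apply_bioassay,
    build_layouts,
    meiosis_female,
    meiosis_male,
    simulate_family,
)


def two_locus_parent(sex="female"):
    """A parent heterozygous at two codominant loci on one group."""
    markers = [
        MarkerDef("A", 1, 10, CODOMINANT, 272, 282),
        MarkerDef("B", 1, 20, CODOMINANT, 264, 250),
    ]
    layouts = build_layouts(markers)
    genome = {1: (layouts[1].allele_res.copy(), layouts[1].allele_sus.copy())}
    return popsim.Individual(id="p", sex=sex, role="F1", genome=genome), layouts


class TestFemaleMeiosis:
    def test_transmits_each_homolog_half_the_time(self):
        parent, _ = two_locus_parent()
        rng = np.random.default_rng(0)
        n = 10_000
        hits = sum(meiosis_female(parent, 1, rng)[0] == 272 for _ in range(n))
        # binomial(10000, 0.5): 3 SD band
        assert abs(hits - n / 2) < 3 * np.sqrt(n * 0.25)

    def test_never_a_mosaic(self):
        parent, _ = two_locus_parent()
        rng = np.random.default_rng(1)
        h0, h1 = parent.genome[1]
        for _ in range(200):
            gamete = meiosis_female(parent, 1, rng)
            assert np.array_equal(gamete, h0) or np.array_equal(gamete, h1)

    def test_homozygous_parent_returns_the_shared_haplotype(self):
        parent, _ = two_locus_parent()
        parent.genome[1] = (parent.genome[1][0], parent.genome[1][0].copy())
        gamete = meiosis_female(parent, 1, np.random.default_rng(2))
        assert np.array_equal(gamete, parent.genome[1][0])

    def test_male_parent_rejected(self):
        parent, _ = two_locus_parent(sex="male")
        with pytest.raises(ValueError, match="female"):
            meiosis_female(parent, 1, np.random.default_rng(0))


class TestMaleMeiosis:
    def test_zero_fractions_give_intact_homolog(self):
        parent, _ = two_locus_parent(sex="male")
        rmap = RecombMap({1: [0.0]})
        rng = np.random.default_rng(3)
        h0, h1 = parent.genome[1]
        for _ in range(100):
            gamete = meiosis_male(parent, 1, rmap, rng)
            assert np.array_equal(gamete, h0) or np.array_equal(gamete, h1)

    def test_half_fraction_means_independent_assortment(self):
        parent, _ = two_locus_parent(sex="male")
        rmap = RecombMap({1: [0.5]})
        rng = np.random.default_rng(4)
        n = 8_000
        counts = {}
        for _ in range(n):
            g = tuple(meiosis_male(parent, 1, rmap, rng))
            counts[g] = counts.get(g, 0) + 1
        assert len(counts) == 4
        for c in counts.values():  # each gamete class ~ n/4
            assert abs(c - n / 4) < 3 * np.sqrt(n * 0.25 * 0.75)

    def test_recombinant_fraction_recovers_map_value(self):
        # the trait-RpL22 interval of the study map: r = 0.10
        parent, _ = two_locus_parent(sex="male")
        rmap = RecombMap({1: [0.10]})
        rng = np.random.default_rng(5)
        n = 10_000
        h0 = parent.genome[1][0]
        rec = 0
        for _ in range(n):
            g = meiosis_male(parent, 1, rmap, rng)
            rec += int((g[0] == h0[0]) != (g[1] == h0[1]))
        se = np.sqrt(0.10 * 0.90 / n)
        assert abs(rec / n - 0.10) < 3 * se

    def test_fraction_vector_length_checked(self):
        parent, _ = two_locus_parent(sex="male")
        with pytest.raises(ValueError, match="fractions"):
            meiosis_male(parent, 1, RecombMap({1: [0.1, 0.1]}), np.random.default_rng(0))

    def test_female_parent_rejected(self):
        parent, _ = two_locus_parent(sex="female")
        with pytest.raises(ValueError, match="male"):
            meiosis_male(parent, 1, RecombMap({1: [0.1]}), np.random.default_rng(0))


class TestBioassay:
    @staticmethod
    def progeny_with(genotype):
        ind = popsim.Individual(
            id="x", sex="female", role="progeny", genome={}, cohort="control"
        )
        ind.trait_genotype = genotype
        return ind

    def test_rr_survives_and_rs_dies_under_default_model(self):
        trait = TraitLocus(group=1, position=5)
        rng = np.random.default_rng(0)
        assert apply_bioassay([self.progeny_with("rr")], trait, rng) == ["treated-survivor"]
        assert apply_bioassay([self.progeny_with("rs")], trait, rng) == ["treated-dead"]
        assert apply_bioassay([self.progeny_with("ss")], trait, rng) == ["treated-dead"]

    def test_false_positive_rate_yields_spurious_survivors(self):
        trait = TraitLocus(group=1, position=5)
        rng = np.random.default_rng(6)
        cohort = [self.progeny_with("rs") for _ in range(10_000)]
        labels = apply_bioassay(cohort, trait, rng, false_positive=0.05)
        n = labels.count("treated-survivor")
        assert abs(n - 500) < 3 * np.sqrt(10_000 * 0.05 * 0.95)


class TestSimulateFamily:
    def test_treated_survivors_are_all_rr(self, f2301):
        family, _, _ = f2301
        survivors = [
            i for i in family.progeny if i.cohort == popsim.COHORT_SURVIVOR
        ]
        assert len(survivors) == 29
        assert all(i.trait_genotype == "rr" for i in survivors)

    def test_about_half_of_treated_backcross_progeny_survive(self):
        markers, trait, rmap = popsim.mapping_panel()
        design = FamilyDesign(
            name="big", informative_sex="male", cross="backcross",
            n_treated=2000, seed=2,
        )
        fam = simulate_family(design, markers, trait, rmap)
        n_surv = sum(i.cohort == popsim.COHORT_SURVIVOR for i in fam.progeny)
        # 1:1 rr:rs in a backcross => ~50% survive the discriminating dose
        assert abs(n_surv - 1000) < 3 * np.sqrt(2000 * 0.25)

    def test_identical_seed_gives_identical_matrices(self):
        markers, trait, rmap = popsim.f2301_panel(n_markers=31, n_groups=31)
        design = popsim.f2301_design(seed=42, n_survivors=10, n_control=10)
        a = simulate_family(design, markers, trait, rmap).genotypes
        b = simulate_family(design, markers, trait, rmap).genotypes
        assert a.equals(b)

    def test_maternal_haplotype_is_never_a_mosaic(self, f2301):
        # every progeny's maternal homolog must equal one grandmaternal
        # homolog at all loci of its group (achiasmatic female meiosis)
        family, markers, trait = f2301
        layouts = build_layouts(markers, trait)
        for ind in family.progeny[:40]:
            for g, lay in layouts.items():
                maternal = ind.genome[g][0]
                assert np.array_equal(maternal, lay.allele_res) or np.array_equal(
                    maternal, lay.allele_sus
                )

    def test_unselected_locus_segregates_1_to_1(self, f2301):
        family, markers, trait = f2301
        controls = [i for i in family.progeny if i.cohort == popsim.COHORT_CONTROL]
        origins = [i.maternal_origin[1] for i in controls]  # group 1: no trait
        n = len(origins)
        assert abs(sum(origins) - n / 2) <= 3 * np.sqrt(n * 0.25) + 1

    def test_trait_without_markers_warns_but_simulates(self):
        markers = [MarkerDef("A", 1, 10, DOMINANT, 1, 0)]
        trait = TraitLocus(group=2, position=5)
        layouts = build_layouts(markers, trait)
        rmap = RecombMap.uniform(layouts, 0.1)
        design = FamilyDesign(
            name="w", informative_sex="female", cross="backcross",
            n_treated=5, n_control=5, seed=1,
        )
        with pytest.warns(UserWarning, match="trait group"):
            fam = simulate_family(design, markers, trait, rmap)
        assert all(i.trait_genotype is not None for i in fam.progeny)


class TestDefinitions:
    def test_dominant_marker_must_have_two_states(self):
        with pytest.raises(ValueError, match="presence"):
            MarkerDef("bad", 1, 0, DOMINANT, 1, 1)

    def test_codominant_sizes_positive(self):
        with pytest.raises(ValueError, match="positive"):
            MarkerDef("bad", 1, 0, CODOMINANT, 0, 282)

    def test_recomb_fractions_bounded(self):
        with pytest.raises(ValueError, match=r"\[0, 0.5\]"):
            RecombMap({1: [0.6]})

    def test_survival_probabilities_bounded(self):
        with pytest.raises(ValueError, match="survival"):
            TraitLocus(group=1, position=0, survival={"rr": 1.2, "rs": 0, "ss": 0})

    def test_duplicate_positions_rejected(self):
        markers = [
            MarkerDef("A", 1, 10, DOMINANT, 1, 0),
            MarkerDef("B", 1, 10, DOMINANT, 0, 1),
        ]
        with pytest.raises(ValueError, match="distinct"):
            build_layouts(markers)
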
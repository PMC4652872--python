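"""Recombination-fraction estimation, pooling, ordering, map rendering."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from lepilink import popsim, recombmap
from lepilink.recombmap import (
    GeneticMap,
    RecombinationEstimate,
    compose_r,
    estimate_r_marker_marker,
    estimate_r_trait_marker,
    haldane_cM,
    infer_paternal_haplotypes,
    order_loci,
    parse_size_pair,
    pool_families,
)

RPL22 = popsim.MarkerDef("RpL22", 1, 30, popsim.CODOMINANT, 272, 282)


def selected_matrix(genotypes):
    """Rows of rr-selected survivors with given RpL22 genotype strings."""
    rows = [
        {"id": f"s{i}", "sex": "female", "role": "progeny",
         "cohort": "treated-survivor", "RpL22": g}
        for i, g in enumerate(genotypes)
    ]
    return pd.DataFrame(rows)


class TestTraitMarkerEstimate:
    def test_zero_heterozygotes_means_tight_linkage(self):
        # the ABCA1-marker situation: 272/272 in 100% of 72 selected progeny
        matrix = selected_matrix(["272/272"] * 72)
        est = estimate_r_trait_marker(matrix, RPL22)
        assert (est.n_informative, est.n_recombinant) == (72, 0)
        assert est.r == 0.0

    def test_heterozygote_fraction_is_r_hat(self):
        matrix = selected_matrix(["272/282"] * 7 + ["272/272"] * 63)
        est = estimate_r_trait_marker(matrix, RPL22)
        assert est.r == pytest.approx(0.10)
        assert est.se == pytest.approx(math.sqrt(0.1 * 0.9 / 70))

    def test_pedigree_incompatible_genotype_excluded(self):
        matrix = selected_matrix(["272/272", "264/264", "272/282"])
        est = estimate_r_trait_marker(matrix, RPL22)
        assert est.n_informative == 2
        assert est.excluded == ["s1"]

    def test_homozygous_f1_marker_uninformative(self):
        hom = popsim.MarkerDef("hom", 1, 5, popsim.CODOMINANT, 272, 272)
        with pytest.raises(ValueError, match="uninformative"):
            estimate_r_trait_marker(selected_matrix(["272/272"]), hom)

    def test_simulation_recovers_map_fractions(self, mapping_family):
        # true fractions from the study map: Bre-5 at 0.16, RpL22 at 0.10
        family, markers, _, _ = mapping_family
        for marker_id, truth in (("Bre-5", 0.16), ("RpL22", 0.10)):
            marker = next(m for m in markers if m.id == marker_id)
            est = estimate_r_trait_marker(family.genotypes, marker)
            assert est.n_informative == 500
            assert abs(est.r - truth) < 3 * math.sqrt(truth * (1 - truth) / 500)

    def test_f2_design_estimates_identically(self):
        # only the paternal meiosis is informative, so an F2 intercross
        # yields the same estimator as the backcross
        markers, trait, rmap = popsim.mapping_panel()
        design = popsim.mapping_design(
            seed=5, n_survivors=400, n_control=0, cross="F2", name="G2020"
        )
        family = popsim.simulate_family(design, markers, trait, rmap)
        marker = next(m for m in markers if m.id == "RpL22")
        est = estimate_r_trait_marker(family.genotypes, marker)
        assert est.n_informative == 400
        assert abs(est.r - 0.10) < 3 * math.sqrt(0.1 * 0.9 / 400)


class TestPaternalHaplotypes:
    def test_subtracting_maternal_allele(self):
        matrix = selected_matrix(["272/282", "272/272"])
        paternal, bad = infer_paternal_haplotypes(matrix, [RPL22])
        assert paternal["RpL22"].tolist() == [282, 272]
        assert bad == []

    def test_inconsistent_cell_flagged_and_masked(self):
        matrix = selected_matrix(["264/264"])
        paternal, bad = infer_paternal_haplotypes(matrix, [RPL22])
        assert bad == [("s0", "RpL22")]
        assert paternal["RpL22"].isna().all()


class TestMarkerMarkerEstimate:
    PHASE = {"A": (1, 2), "B": (3, 4)}

    def test_concordant_sources_give_zero(self):
        paternal = pd.DataFrame({"A": [1, 2, 1], "B": [3, 4, 3]}, dtype="Int64")
        est = estimate_r_marker_marker(paternal, "A", "B", self.PHASE)
        assert (est.n_informative, est.n_recombinant) == (3, 0)

    def test_one_recombinant_in_ten(self):
        sources = [(1, 3)] * 9 + [(1, 4)]
        paternal = pd.DataFrame(
            {"A": [s[0] for s in sources], "B": [s[1] for s in sources]},
            dtype="Int64",
        )
        est = estimate_r_marker_marker(paternal, "A", "B", self.PHASE)
        assert est.r == pytest.approx(0.1)
        assert est.se == pytest.approx(math.sqrt(0.1 * 0.9 / 10), rel=1e-6)

    def test_unknown_phase_is_an_error(self):
        paternal = pd.DataFrame({"A": [1], "B": [3]}, dtype="Int64")
        with pytest.raises(ValueError, match="phase"):
            estimate_r_marker_marker(paternal, "A", "B", {"A": (1, 2)})

    def test_simulation_recovers_interval_fraction(self, mapping_family):
        # RpL22 - RpS24 sit 0.06 apart in the male map
        family, markers, _, _ = mapping_family
        phase = {m.id: (m.allele_res, m.allele_sus) for m in markers}
        paternal, _ = infer_paternal_haplotypes(family.genotypes, markers)
        est = estimate_r_marker_marker(paternal, "RpL22", "RpS24", phase)
        assert est.n_informative == 500
        assert abs(est.r - 0.06) < 3 * math.sqrt(0.06 * 0.94 / 500)


class TestPooling:
    def test_pooled_counts_are_summed(self):
        fam_a = RecombinationEstimate("R", "M", 20, 2, per_family={"a": (20, 2)})
        fam_b = RecombinationEstimate("R", "M", 52, 5, per_family={"b": (52, 5)})
        pooled = pool_families([fam_a, fam_b])
        assert (pooled.n_informative, pooled.n_recombinant) == (72, 7)
        assert pooled.r == pytest.approx(7 / 72)
        assert pooled.per_family == {"a": (20, 2), "b": (52, 5)}

    def test_single_family_is_identity(self):
        est = RecombinationEstimate("R", "M", 10, 1)
        pooled = pool_families([est])
        assert (pooled.n_informative, pooled.n_recombinant) == (10, 1)

    def test_mismatched_pairs_rejected(self):
        with pytest.raises(ValueError, match="pairs"):
            pool_families(
                [RecombinationEstimate("R", "M", 5, 0),
                 RecombinationEstimate("R", "Q", 5, 0)]
            )

    def test_zero_informative_meioses_rejected(self):
        with pytest.raises(ValueError, match="zero informative"):
            pool_families([RecombinationEstimate("R", "M", 0, 0)])


def chain_pairwise(order, adjacent):
    """All pairwise fractions of a chain, composed without interference."""
    table = {}
    for i, a in enumerate(order):
        for j in range(i + 1, len(order)):
            r = adjacent[i]
            for k in range(i + 1, j):
                r = compose_r(r, adjacent[k])
            table[(a, order[j])] = r
    return table


class TestOrdering:
    def test_study_map_order_and_rendering(self):
        order = ["Bre-5", "R", "RpL22", "RpS24"]
        table = chain_pairwise(order, [0.16, 0.10, 0.06])
        gmap = order_loci(table)
        assert list(gmap.loci) == order
        assert gmap.render() == "Bre-5–(0.16)–R–(0.10)–RpL22–(0.06)–RpS24"

    def test_two_loci_trivial(self):
        gmap = order_loci({("A", "B"): 0.2})
        assert gmap.loci == ("A", "B")
        assert gmap.adjacent_r == (0.2,)

    def test_matches_exhaustive_oracle_on_random_maps(self):
        # brute-force minimum adjacent-r sum over all permutations
        rng = np.random.default_rng(99)
        for _ in range(100):
            n = int(rng.integers(4, 7))
            loci = [f"L{i}" for i in range(n)]
            order = list(rng.permutation(loci))
            adjacent = rng.uniform(0.02, 0.3, size=n - 1)
            table = chain_pairwise(order, list(adjacent))
            gmap = order_loci(table)
            norm = {frozenset(k): v for k, v in table.items()}

            def cost(perm):
                return sum(
                    norm[frozenset(p)] for p in zip(perm, perm[1:])
                )

            best = min(cost(p) for p in itertools.permutations(loci))
            assert cost(gmap.loci) == pytest.approx(best)

    def test_missing_pair_is_an_error(self):
        with pytest.raises(ValueError, match="missing pairwise"):
            order_loci({("A", "B"): 0.1, ("B", "C"): 0.1}, loci=["A", "B", "C"])

    def test_greedy_seriation_recovers_long_chains(self):
        order = [f"L{i:02d}" for i in range(10)]
        adjacent = [0.05] * 9
        table = chain_pairwise(order, adjacent)
        gmap = order_loci(table, exhaustive_max=8)
        assert list(gmap.loci) in (order, order[::-1])


class TestHaldane:
    @pytest.mark.parametrize(
        "r,expected",
        [(0.0, 0.0), (0.10, 11.157), (0.16, 19.283)],
    )
    def test_closed_form_values(self, r, expected):
        assert haldane_cM(r) == pytest.approx(expected, abs=5e-3)

    def test_unlinked_fraction_maps_to_infinity(self):
        assert math.isinf(haldane_cM(0.5))

    def test_negative_fraction_rejected(self):
        with pytest.raises(ValueError):
            haldane_cM(-0.01)


class TestEstimatorProperties:
    def test_unbiased_over_replicates(self):
        # mean r-hat within 3 Monte-Carlo SE of truth at the map fractions
        markers, trait, rmap = popsim.mapping_panel()
        truths = {"Bre-5": 0.16, "RpL22": 0.10}
        n_reps, n_sel = 60, 150
        sums = {m: 0.0 for m in truths}
        for rep in range(n_reps):
            design = popsim.mapping_design(
                seed=3_000 + rep, n_survivors=n_sel, n_control=0
            )
            family = popsim.simulate_family(design, markers, trait, rmap)
            for mid in truths:
                marker = next(m for m in markers if m.id == mid)
                est = estimate_r_trait_marker(family.genotypes, marker)
                sums[mid] += est.r
        for mid, truth in truths.items():
            mean = sums[mid] / n_reps
            mc_se = math.sqrt(truth * (1 - truth) / n_sel / n_reps)
            assert abs(mean - truth) < 3 * mc_se, mid

    def test_chromosome_walk_monotonicity(self):
        # expected r-hat to the trait shrinks as markers approach the locus
        group = 1
        fractions = [0.08, 0.08, 0.08, 0.08]
        markers = [
            popsim.MarkerDef(f"W{i}", group, 10 * (i + 1), popsim.CODOMINANT,
                             200 + 10 * i, 205 + 10 * i)
            for i in range(4)
        ]
        trait = popsim.TraitLocus(group=group, position=55)  # beyond W3
        rmap = popsim.RecombMap({group: fractions})
        design = popsim.mapping_design(seed=77, n_survivors=3000, n_control=0)
        family = popsim.simulate_family(design, markers, trait, rmap)
        rs = [
            estimate_r_trait_marker(family.genotypes, m).r for m in markers
        ]
        assert rs == sorted(rs, reverse=True)
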
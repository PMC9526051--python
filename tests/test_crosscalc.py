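"""Exact gamete, offspring, and seed-class probability calculations."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trafficlines import crosscalc as cc
from trafficlines.crosscalc import CrossDesign, GeneticMap, Locus, SeedClassModel


def marker_pair_map(r: float, c: float = 1.0) -> GeneticMap:
    return GeneticMap(
        [
            Locus("G", alleles=("+", "G"), channel="green"),
            Locus("R", alleles=("+", "R"), channel="red"),
        ],
        [r],
        c=c,
    )


def three_point_map(r1: float, r2: float, c: float = 1.0) -> GeneticMap:
    return GeneticMap(
        [
            Locus("G", alleles=("+", "G"), channel="green"),
            Locus("M", alleles=("+", "m")),
            Locus("R", alleles=("+", "R"), channel="red"),
        ],
        [r1, r2],
        c=c,
    )


def balanced_cross(r1: float, r2: float, c: float = 1.0) -> CrossDesign:
    """Self of a (G + R)/(+ m +) heterozygote: mutation in trans to the TL."""
    return CrossDesign(three_point_map(r1, r2, c), (("G", "+", "R"), ("+", "m", "+")))


def p_homozygous(post, gmap, name, allele):
    i = gmap.locus_index(name)
    return sum(p for dip, p in post.items() if dip[0][i] == allele and dip[1][i] == allele)


class TestGameteDistribution:
    def test_no_recombination_gives_parentals_only(self):
        gm = three_point_map(0.0, 0.0, c=0.7)
        dist = cc.gamete_distribution((("G", "+", "R"), ("+", "m", "+")), gm)
        assert dist == {("G", "+", "R"): 0.5, ("+", "m", "+"): 0.5}

    def test_repulsion_two_point_classes(self):
        dist = cc.gamete_distribution((("G", "+"), ("+", "R")), marker_pair_map(0.078))
        assert dist[("G", "+")] == pytest.approx(0.461)
        assert dist[("+", "R")] == pytest.approx(0.461)
        assert dist[("G", "R")] == pytest.approx(0.039)
        assert dist[("+", "+")] == pytest.approx(0.039)

    def test_double_recombinant_haplotype_mass(self):
        gm = three_point_map(0.035, 0.035, c=1.0)
        dist = cc.gamete_distribution((("G", "+", "R"), ("+", "m", "+")), gm)
        assert dist[("G", "m", "R")] == pytest.approx(0.035 * 0.035 / 2)
        assert dist[("+", "+", "+")] == pytest.approx(0.035 * 0.035 / 2)

    def test_reciprocal_haplotypes_equal_probability(self):
        gm = three_point_map(0.1, 0.2, c=0.4)
        dist = cc.gamete_distribution((("G", "+", "R"), ("+", "m", "+")), gm)
        # reciprocal = same exchange pattern starting from the other strand
        assert dist[("G", "+", "R")] == pytest.approx(dist[("+", "m", "+")])
        assert dist[("G", "m", "R")] == pytest.approx(dist[("+", "+", "+")])
        assert dist[("G", "m", "+")] == pytest.approx(dist[("+", "+", "R")])

    def test_marginal_two_locus_fraction_identity(self):
        r1, r2, c = 0.1, 0.2, 0.5
        gm = three_point_map(r1, r2, c)
        dist = cc.gamete_distribution((("G", "+", "R"), ("+", "m", "+")), gm)
        # recombinant between the outer loci = exchange in exactly one segment
        rec = sum(p for hap, p in dist.items() if (hap[0] == "G") != (hap[2] == "R"))
        assert rec == pytest.approx(r1 + r2 - 2 * c * r1 * r2, abs=1e-12)

    def test_too_many_linked_loci_points_to_simulator(self):
        loci = [Locus(f"L{i}", alleles=("+", f"a{i}")) for i in range(4)]
        gm = GeneticMap(loci, [0.1, 0.1, 0.1])
        with pytest.raises(ValueError, match="meiosim"):
            cc.gamete_distribution(
                (("+", "+", "+", "+"), ("a0", "a1", "a2", "a3")), gm
            )

    def test_collapsing_interior_locus_reproduces_two_point(self):
        r1, r2 = 0.03, 0.05
        gm3 = three_point_map(r1, r2, c=1.0)
        dist3 = cc.gamete_distribution((("G", "+", "R"), ("+", "m", "+")), gm3)
        r_total = r1 + r2 - 2 * r1 * r2
        # markers are in cis in the three-point parent, so compare against a
        # cis two-point parent at the marginal fraction
        dist2 = cc.gamete_distribution((("G", "R"), ("+", "+")), marker_pair_map(r_total))
        for g_allele in ("G", "+"):
            for r_allele in ("R", "+"):
                collapsed = sum(
                    p for hap, p in dist3.items() if hap[0] == g_allele and hap[2] == r_allele
                )
                assert collapsed == pytest.approx(dist2[(g_allele, r_allele)], abs=1e-12)

    @given(
        st.floats(0.0, 0.5), st.floats(0.0, 0.5), st.floats(0.0, 1.0)
    )
    @settings(max_examples=60, derandomize=True)
    def test_distribution_is_normalized_and_nonnegative(self, r1, r2, c):
        gm = three_point_map(r1, r2, c)
        dist = cc.gamete_distribution((("G", "+", "R"), ("+", "m", "+")), gm)
        assert all(p >= 0.0 for p in dist.values())
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)


class TestClosedForms:
    def test_double_recombination_is_about_one_per_thousand(self):
        # half of the catalog's average 6.9 cM on each side of a midpoint locus
        assert cc.double_recombinant_freq(0.035, 0.035, 1.0) == pytest.approx(0.001225)
        assert round(cc.double_recombinant_freq(0.035, 0.035, 1.0), 3) == 0.001

    def test_complete_interference_kills_doubles(self):
        assert cc.double_recombinant_freq(0.3, 0.4, 0.0) == 0.0

    def test_matches_double_class_mass_of_gamete_distribution(self):
        r1, r2, c = 0.1, 0.2, 0.5
        gm = three_point_map(r1, r2, c)
        dist = cc.gamete_distribution((("G", "+", "R"), ("+", "m", "+")), gm)
        doubles = dist[("G", "m", "R")] + dist[("+", "+", "+")]
        assert doubles == pytest.approx(cc.double_recombinant_freq(r1, r2, c))
        assert cc.double_recombinant_freq(r1, r2, c) == pytest.approx(0.01)

    def test_purity_leak_zero_at_a_marker(self):
        assert cc.balancer_purity(0.0, 0.07, 1.0) == 0.0

    def test_purity_leak_closed_form_value(self):
        assert cc.balancer_purity(0.035, 0.035, 1.0) == pytest.approx(0.0013137, abs=5e-7)

    def test_leak_maximal_at_interval_midpoint(self):
        total = 0.07
        leaks = [cc.balancer_purity(x, total - x, 1.0) for x in
                 (0.005, 0.015, 0.025, 0.035, 0.045, 0.055, 0.065)]
        mid = len(leaks) // 2
        assert leaks[mid] == max(leaks)
        assert all(leaks[i] < leaks[i + 1] for i in range(mid))
        assert all(leaks[i] > leaks[i + 1] for i in range(mid, len(leaks) - 1))

    def test_leak_agrees_with_conditional_from_gamete_distribution(self):
        r1, r2, c = 0.04, 0.02, 0.6
        gm = three_point_map(r1, r2, c)
        dist = cc.gamete_distribution((("G", "m_tl", "R"), ("+", "+", "+")), gm)
        no_marker = {h: p for h, p in dist.items() if h[0] == "+" and h[2] == "+"}
        leak = no_marker.get(("+", "m_tl", "+"), 0.0) / sum(no_marker.values())
        assert leak == pytest.approx(cc.balancer_purity(r1, r2, c), abs=1e-12)


class TestOffspring:
    def test_mendelian_self(self):
        gm = GeneticMap([Locus("A", alleles=("A", "a"))], [])
        cross = CrossDesign(gm, (("A",), ("a",)))
        dist = cc.offspring_distribution(cross)
        assert dist[(("A",), ("A",))] == pytest.approx(0.25)
        assert dist[(("A",), ("a",))] == pytest.approx(0.5)
        assert dist[(("a",), ("a",))] == pytest.approx(0.25)

    def test_testcross_offspring_mirror_gamete_classes(self):
        gm = marker_pair_map(0.078)
        het = (("G", "+"), ("+", "R"))
        tester = (("+", "+"), ("+", "+"))
        dist = cc.offspring_distribution(CrossDesign(gm, het, tester))
        gametes = cc.gamete_distribution(het, gm)
        for hap, p in gametes.items():
            assert dist[cc.diplotype_key(hap, ("+", "+"))] == pytest.approx(p)

    def test_mismatched_haplotype_length_rejected(self):
        gm = marker_pair_map(0.1)
        with pytest.raises(ValueError):
            CrossDesign(gm, (("G",), ("+",)))

    def test_offspring_distribution_normalized(self):
        dist = cc.offspring_distribution(balanced_cross(0.1, 0.2, 0.5))
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)


class TestSeedClasses:
    def test_balanced_self_without_recombination(self):
        # TL/m self, r = 0: 1/4 strong both, 1/2 moderate both, 1/4 nonfluorescent dead
        cross = balanced_cross(0.0, 0.0)
        offspring = cc.offspring_distribution(cross)
        dist = cc.seed_class_distribution(
            offspring, cross.map, lethal=[{"M": "m"}]
        )
        assert dist[("strong", "strong", True, "")] == pytest.approx(0.25)
        assert dist[("moderate", "moderate", True, "")] == pytest.approx(0.5)
        assert dist[("none", "none", False, "")] == pytest.approx(0.25)
        fluor = sum(p for (g, r, _, _), p in dist.items() if g != "none" or r != "none")
        assert fluor == pytest.approx(0.75)

    def test_distribution_normalized_with_confusion(self):
        cross = balanced_cross(0.045, 0.045)
        dist = cc.seed_class_distribution(
            cc.offspring_distribution(cross), cross.map, SeedClassModel(epsilon=0.03)
        )
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)
        assert all(p >= 0 for p in dist.values())

    def test_zero_epsilon_inversion_is_identity_on_distinguishable_classes(self):
        cross = balanced_cross(0.0, 0.0)
        post = cc.genotype_posterior(cross, ("strong", "strong"))
        assert post == {((("G", "+", "R")), ("G", "+", "R")): pytest.approx(1.0)}

    def test_albino_posterior_sharpens_as_r_shrinks(self):
        gm = balanced_cross(0.045, 0.045).map
        vals = []
        for r in (0.045, 0.01, 0.001):
            post = cc.genotype_posterior(balanced_cross(r, r), "nonfluorescent")
            vals.append(p_homozygous(post, gm, "M", "m"))
        assert vals[0] < vals[1] < vals[2]
        assert vals[2] > 0.999

    def test_moderate_class_concordance_with_misreading(self):
        # seed-by-fluorescence genotyping stays ~97% reliable with a few
        # percent of adjacent-intensity misreads
        cross = balanced_cross(0.045, 0.045)
        post = cc.genotype_posterior(cross, "moderate_both", SeedClassModel(epsilon=0.03))
        i = cross.map.locus_index("M")
        p_het = sum(
            p for dip, p in post.items() if sorted((dip[0][i], dip[1][i])) == ["+", "m"]
        )
        assert 0.95 < p_het < 1.0
        post0 = cc.genotype_posterior(cross, "moderate_both", SeedClassModel(epsilon=0.0))
        p_het0 = sum(
            p for dip, p in post0.items() if sorted((dip[0][i], dip[1][i])) == ["+", "m"]
        )
        assert p_het < p_het0  # misreading dilutes concordance


class TestGenotypePosterior:
    def test_unlinked_tl_gives_three_to_one(self):
        # F2 of mutant x TL on another chromosome: fluorescent seeds are 1/4 mutant
        loci = [
            Locus("G", 1, alleles=("+", "G"), channel="green"),
            Locus("R", 1, alleles=("+", "R"), channel="red"),
            Locus("MUT", 4, alleles=("+", "m")),
        ]
        gm = GeneticMap(loci, {1: [0.069], 4: []})
        cross = CrossDesign(gm, (("G", "R", "m"), ("+", "+", "+")))
        post = cc.genotype_posterior(cross, "fluorescent")
        assert p_homozygous(post, gm, "MUT", "m") == pytest.approx(0.25)

    def test_midpoint_nonfluorescent_closed_form(self):
        r1 = r2 = 0.042
        c = 1.0
        post = cc.genotype_posterior(balanced_cross(r1, r2, c), "nonfluorescent")
        expected = ((1 - r1 - r2 + c * r1 * r2) / (1 - r1 - r2 + 2 * c * r1 * r2)) ** 2
        gm = balanced_cross(r1, r2, c).map
        assert p_homozygous(post, gm, "M", "m") == pytest.approx(expected, abs=1e-12)

    def test_no_recombination_makes_nonfluorescent_homozygous(self):
        post = cc.genotype_posterior(balanced_cross(0.0, 0.0), "nonfluorescent")
        gm = balanced_cross(0.0, 0.0).map
        assert p_homozygous(post, gm, "M", "m") == pytest.approx(1.0)

    def test_zero_probability_class_rejected(self):
        cross = balanced_cross(0.0, 0.0)
        with pytest.raises(ValueError, match="zero probability"):
            cc.genotype_posterior(cross, ("strong", "none"))


class TestSchemes:
    def test_rescue_without_transformation_or_recombination(self):
        cats = cc.rescue_scheme(0.0, 0.0, tau=0.0)
        assert cats["fluorescent_viable"] == pytest.approx(0.75)
        assert cats["nonfluorescent_dead"] == pytest.approx(0.25)
        assert cats["nonfluorescent_rescued_homozygote"] == 0.0
        assert cats["nonfluorescent_double_recombinant_het"] == 0.0

    def test_untransformed_nonfluorescent_survivors_are_double_recombinants(self):
        cats = cc.rescue_scheme(0.042, 0.042, tau=0.0)
        survivors = (
            cats["nonfluorescent_rescued_homozygote"]
            + cats["nonfluorescent_double_recombinant_het"]
            + cats["nonfluorescent_wildtype_homozygote"]
        )
        assert cats["nonfluorescent_rescued_homozygote"] == 0.0
        assert cats["nonfluorescent_double_recombinant_het"] > 0.0
        assert cats["nonfluorescent_double_recombinant_het"] / survivors > 0.99

    def test_rescued_vs_double_recombinant_ratio(self):
        r1 = r2 = 0.042
        tau = 0.01
        cats = cc.rescue_scheme(r1, r2, tau=tau)
        # both parental no-marker gametes -> m/m; rescued at rate tau
        p_none_parental = (1 - r1 - r2 + r1 * r2) / 2
        p_none_double = r1 * r2 / 2
        p_nonfluor_mm = p_none_parental**2
        p_nonfluor_het = 2 * p_none_parental * p_none_double
        assert cats["nonfluorescent_rescued_homozygote"] == pytest.approx(tau * p_nonfluor_mm)
        assert cats["nonfluorescent_double_recombinant_het"] == pytest.approx(p_nonfluor_het)
        assert sum(cats.values()) == pytest.approx(1.0, abs=1e-12)

    def test_separation_symmetric_limit(self):
        # vanishing middle segment: the two major recombinant classes split evenly
        dist = cc.separation_scheme(0.011, 1e-9, 0.011)
        assert dist["m1 m2"] == pytest.approx(0.5, abs=1e-3)
        assert dist["+ +"] == pytest.approx(0.5, abs=1e-3)
        assert dist.get("m1 +", 0.0) < 1e-6

    def test_separation_mixed_class_scales_with_middle_segment(self):
        # 0.6 Mb / 45 kb / 0.6 Mb at a uniform local rate
        dist = cc.separation_scheme(0.0108, 0.00081, 0.0108)
        mixed = dist.get("m1 +", 0.0) + dist.get("+ m2", 0.0)
        assert mixed == pytest.approx(45 / 1245, rel=0.05)

    def test_separation_selected_class_is_purely_single_recombinant_at_zero_eps(self):
        dist = cc.separation_scheme(0.0108, 0.00081, 0.0108, epsilon=0.0)
        assert dist.get("other", 0.0) == 0.0
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)

    def test_separation_misreads_leak_in_nonrecombinants(self):
        dist = cc.separation_scheme(0.0108, 0.00081, 0.0108, epsilon=0.03)
        assert dist["other"] > 0.0

    def test_separation_mirror_selection_symmetry(self):
        a = cc.separation_scheme(0.01, 0.002, 0.01, selected="strong_red_moderate_green")
        b = cc.separation_scheme(0.01, 0.002, 0.01, selected="strong_green_moderate_red")
        assert a["m1 m2"] == pytest.approx(b["m1 m2"], abs=1e-12)
        # the single-mutant class swaps sides under the mirrored selection
        assert a.get("m1 +", 0.0) == pytest.approx(b.get("+ m2", 0.0), abs=1e-12)


class TestSampleSize:
    @pytest.mark.parametrize(
        "p, conf, expected",
        [(0.5, 0.95, 5), (0.001, 0.95, 2995), (1 - 1e-9, 0.99, 1)],
    )
    def test_known_values(self, p, conf, expected):
        assert cc.sample_size(p, conf) == expected

    def test_guarantee_holds_and_is_tight(self):
        for p in (0.3, 0.01, 0.123):
            n = cc.sample_size(p, 0.95)
            assert 1 - (1 - p) ** n >= 0.95
            assert 1 - (1 - p) ** (n - 1) < 0.95

    def test_impossible_event_rejected(self):
        with pytest.raises(ValueError):
            cc.sample_size(0.0, 0.95)
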
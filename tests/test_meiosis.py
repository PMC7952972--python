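"""Gamete enumeration, imbalance bookkeeping and euploidy probabilities."""

from fractions import Fraction
from itertools import combinations

import pytest

import pgtcnv as P
from pgtcnv.meiosis import SegregationWeights, balanced_mass


@pytest.fixture(scope="module")
def recip(full_map):
    k = P.resolve_breakpoints(
        P.parse_karyotype("46,XX,t(2;8)(q24;p22)"), full_map)
    return k.rearrangements[0]


@pytest.fixture(scope="module")
def rob(full_map):
    k = P.resolve_breakpoints(
        P.parse_karyotype("45,XY,rob(13;14)(q10;q10)"), full_map)
    return k.rearrangements[0]


class TestReciprocalEnumeration:
    def test_counseling_convention_balanced_mass(self, recip, full_map):
        classes = P.enumerate_gametes(recip, full_map)
        balanced = [c for c in classes if c.balanced]
        assert len(balanced) == 2
        assert {c.mode for c in balanced} == {"alternate"}
        assert sum(c.weight for c in balanced) == Fraction(1, 9)

    def test_distinct_convention(self, recip, full_map):
        w = SegregationWeights(reciprocal_convention="distinct")
        classes = P.enumerate_gametes(recip, full_map, w)
        assert len(classes) == 16
        assert sum(c.weight for c in classes if c.balanced) == Fraction(1, 8)
        assert all(c.weight == Fraction(1, 16) for c in classes)

    def test_brute_force_subset_oracle(self, recip, full_map):
        """Independently enumerate all subsets of the 4 quadrivalent
        elements, bucket by segregation arity, and confirm the class
        compositions match."""
        classes = P.enumerate_gametes(
            recip, full_map, SegregationWeights(reciprocal_convention="distinct"))
        elements = ("A", "B", "derA", "derB")
        expected = set()
        for r in range(5):
            for sub in combinations(elements, r):
                expected.add(frozenset(sub) if len(set(sub)) == len(sub)
                             else None)
        got = {frozenset(c.elements) for c in classes}
        assert got == {s for s in expected if s is not None}
        # arity buckets: 6 two:two, 8 three:one (4 trios + 4 singles),
        # 2 four:zero
        sizes = sorted(len(c.elements) for c in classes)
        assert sizes.count(2) == 6
        assert sizes.count(3) == 4 and sizes.count(1) == 4
        assert sizes.count(4) == 1 and sizes.count(0) == 1

    def test_complementary_classes_conserve_quadrivalent(self, recip, full_map):
        """For each 2:2 split the two poles' segment contents sum to the
        full quadrivalent (two copies of every segment)."""
        classes = P.enumerate_gametes(recip, full_map)
        by_elements = {frozenset(c.elements): c for c in classes}
        elements = frozenset(("A", "B", "derA", "derB"))
        for c in classes:
            if len(c.elements) != 2:
                continue
            mate = by_elements[elements - frozenset(c.elements)]
            total = {}
            for seg, n in list(c.segments) + list(mate.segments):
                total[seg] = total.get(seg, 0) + n
            assert set(total.values()) == {2}

    def test_weights_sum_to_one_all_kinds(self, full_map):
        karyotypes = ["46,XX,t(2;8)(q24;p22)", "45,XY,rob(13;14)(q10;q10)",
                      "46,XX,inv(9)(p12q13)", "46,XX,inv(7)(q22q34)",
                      "46,X,del(X)(p22.2p22.33)", "46,Y,dup(X)(q21.31q22.1)"]
        for text in karyotypes:
            k = P.resolve_breakpoints(P.parse_karyotype(text), full_map)
            classes = P.enumerate_gametes(k.rearrangements[0], full_map)
            assert sum(c.weight for c in classes) == 1


class TestRobertsonian:
    def test_eight_classes_two_balanced(self, rob, full_map):
        classes = P.enumerate_gametes(rob, full_map)
        assert len(classes) == 8
        balanced = [c for c in classes if c.balanced]
        assert len(balanced) == 2
        assert {frozenset(c.elements) for c in balanced} == {
            frozenset({"der"}), frozenset({"A", "B"})}
        assert sum(c.weight for c in balanced) == Fraction(1, 4)

    def test_unbalanced_products_cover_all_four_aneuploidies(self, rob,
                                                             full_map):
        """Trivalent 2:1 splits give disomic/nullisomic gametes for both
        chromosomes: trisomy-13, monosomy-13, trisomy-14, monosomy-14
        zygotes (with a normal partner gamete)."""
        classes = P.enumerate_gametes(rob, full_map)
        deltas = set()
        for c in classes:
            if c.balanced:
                continue
            prof = P.gamete_imbalance(c)
            for reg in prof.regions:
                deltas.add((reg.chrom, reg.delta))
        assert {("13", 1), ("13", -1), ("14", 1), ("14", -1)} <= deltas


class TestInversion:
    def test_pericentric_recombinants_dup_one_flank_del_other(self, full_map):
        k = P.resolve_breakpoints(
            P.parse_karyotype("46,XX,inv(9)(p12q13)"), full_map)
        classes = P.enumerate_gametes(k.rearrangements[0], full_map)
        assert len(classes) == 4
        balanced = [c for c in classes if c.balanced]
        assert len(balanced) == 2 and all(c.mode == "non-recombinant"
                                          for c in balanced)
        recs = [c for c in classes if c.mode == "recombinant"]
        assert all(c.viable for c in recs)
        for c in recs:
            prof = P.gamete_imbalance(c)
            signs = sorted(r.delta for r in prof.regions)
            assert signs == [-1, 1]  # one flank duplicated, one deleted

    def test_paracentric_recombinants_nonviable(self, full_map):
        k = P.resolve_breakpoints(
            P.parse_karyotype("46,XX,inv(7)(q22q34)"), full_map)
        classes = P.enumerate_gametes(k.rearrangements[0], full_map)
        recs = [c for c in classes if c.mode == "recombinant"]
        assert recs and all(not c.viable for c in recs)


class TestImbalance:
    def test_balanced_gamete_empty_profile(self, recip, full_map):
        for c in P.enumerate_gametes(recip, full_map):
            if c.balanced:
                assert P.gamete_imbalance(c).balanced

    def test_adjacent1_partial_trisomy_plus_partial_monosomy(self, recip,
                                                             full_map):
        classes = P.enumerate_gametes(recip, full_map)
        adj1 = [c for c in classes if c.mode == "adjacent-1"]
        assert len(adj1) == 2
        for c in adj1:
            regions = P.gamete_imbalance(c).regions
            deltas = sorted(r.delta for r in regions)
            assert deltas == [-1, 1]
            assert {r.chrom for r in regions} == {"2", "8"}

    def test_interchange_trisomy_is_whole_chromosome(self, recip, full_map):
        classes = P.enumerate_gametes(recip, full_map)
        tri = next(c for c in classes
                   if frozenset(c.elements) == frozenset({"A", "derA", "derB"}))
        regions = P.gamete_imbalance(tri).regions
        whole = [r for r in regions
                 if r.start == 0 and r.end == full_map.lengths[r.chrom]]
        assert any(r.chrom == "2" and r.delta == 1 for r in whole)


class TestZygote:
    def test_balanced_times_balanced_empty(self, recip, full_map):
        classes = P.enumerate_gametes(recip, full_map)
        bal = next(c for c in classes if c.balanced)
        assert P.zygote_profile(bal, bal).balanced

    def test_additivity_with_normal_partner(self, recip, full_map):
        classes = P.enumerate_gametes(recip, full_map)
        adj1 = next(c for c in classes if c.mode == "adjacent-1")
        normal = P.enumerate_gametes(None, full_map)[0]
        z = P.zygote_profile(adj1, normal)
        assert z.regions == P.gamete_imbalance(adj1).regions

    def test_null_times_null_is_nullisomy_not_error(self, recip, full_map):
        # the empty 4:0 pole from both parents drives the involved
        # chromosomes to copy 0, which is valid nullisomy
        classes = P.enumerate_gametes(recip, full_map)
        empty = next(c for c in classes if not c.elements)
        z = P.zygote_profile(empty, empty)
        assert all(r.delta == -2 for r in z.regions)

    def test_copy_below_zero_rejected(self):
        from pgtcnv.meiosis import ImbalanceProfile, ImbalanceRegion
        a = ImbalanceProfile((ImbalanceRegion("1", 0, 10**6, -2),))
        b = ImbalanceProfile((ImbalanceRegion("1", 0, 10**6, -1),))
        with pytest.raises(ValueError, match="below zero"):
            P.zygote_profile(a, b)


class TestCoupleEuploidy:
    def test_double_reciprocal_carrier_couple_is_one_in_81(self, full_map):
        km = P.resolve_breakpoints(
            P.parse_karyotype("46,XX,t(2;8)(q24;p22)"), full_map)
        kf = P.resolve_breakpoints(
            P.parse_karyotype("46,XY,t(11;22)(q23;q11.2)"), full_map)
        p = P.couple_euploid_probability(km, kf, full_map)
        assert p == Fraction(1, 81)

    def test_normal_couple_probability_one(self, full_map):
        km = P.parse_karyotype("46,XX")
        kf = P.parse_karyotype("46,XY")
        assert P.couple_euploid_probability(km, kf, full_map) == 1

    def test_single_carrier_times_normal_is_one_ninth(self, full_map):
        km = P.resolve_breakpoints(
            P.parse_karyotype("46,XX,t(2;8)(q24;p22)"), full_map)
        kf = P.parse_karyotype("46,XY")
        assert P.couple_euploid_probability(km, kf, full_map) == Fraction(1, 9)

    def test_multiplicative_and_bounded(self, full_map):
        km = P.resolve_breakpoints(
            P.parse_karyotype("45,XX,rob(13;14)(q10;q10)"), full_map)
        kf = P.resolve_breakpoints(
            P.parse_karyotype("46,XY,t(11;22)(q23;q11.2)"), full_map)
        p = P.couple_euploid_probability(km, kf, full_map)
        assert p == balanced_mass(km, full_map) * balanced_mass(kf, full_map)
        assert 0 <= p <= 1
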
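import itertools

import numpy as np
import pytest

from transinteract import (
    BindingSite,
    SiteCatalog,
    classify_pairs,
    fraction_sites_overlapped,
    pool_sites,
    randomize_sites,
    sites_overlap,
)
from transinteract.overlap_engine import randomized_placement

from conftest import make_utr


def rbp_site(reg, start, end, gene="G1"):
    return BindingSite(reg, "RBP", gene, start, end)


class TestSitesOverlap:
    def test_one_nucleotide_intersection(self):
        assert sites_overlap(rbp_site("A", 0, 10), rbp_site("B", 9, 20))

    def test_half_open_adjacency_is_not_overlap(self):
        assert not sites_overlap(rbp_site("A", 0, 10), rbp_site("B", 10, 20))

    def test_gap_below_max_gap_counts(self):
        a, b = rbp_site("A", 0, 10), rbp_site("B", 13, 20)
        assert not sites_overlap(a, b)
        assert sites_overlap(a, b, max_gap=5)  # gap of 3 < 5

    def test_gap_equal_to_max_gap_does_not_count(self):
        a, b = rbp_site("A", 0, 10), rbp_site("B", 15, 20)
        assert not sites_overlap(a, b, max_gap=5)

    def test_symmetry(self):
        a, b = rbp_site("A", 3, 12), rbp_site("B", 10, 14)
        assert sites_overlap(a, b) == sites_overlap(b, a)

    def test_different_genes_rejected(self):
        with pytest.raises(ValueError):
            sites_overlap(rbp_site("A", 0, 10), rbp_site("B", 0, 10, gene="G2"))


class TestClassifyPairs:
    def test_overlapping_trio(self, two_site_catalog):
        trios, _ = classify_pairs(two_site_catalog)
        (t,) = trios
        assert t.scenario == "overlapping"
        assert t.n_overlapping_site_pairs == 1
        assert t.pair_id == ("RBP1", "RBP2")

    def test_neighboring_trio(self):
        utrs = {"G1": make_utr("G1", 100)}
        cat = pool_sites(utrs, [rbp_site("RBP1", 0, 10), rbp_site("RBP2", 50, 60)])
        trios, _ = classify_pairs(cat)
        assert trios[0].scenario == "neighboring"

    def test_pair_without_shared_gene_flagged_independent(self):
        utrs = {g: make_utr(g, 100) for g in ("G1", "G2")}
        cat = pool_sites(utrs, [rbp_site("RBP1", 0, 10, "G1"),
                                rbp_site("RBP2", 0, 10, "G2")])
        trios, summary = classify_pairs(cat)
        assert trios == []
        assert summary["pair_label"].tolist() == ["independent"]

    def test_class_filter_restricts_pairs(self):
        utrs = {"G1": make_utr("G1", 100)}
        sites = [rbp_site("RBP1", 0, 10), rbp_site("RBP2", 5, 15),
                 BindingSite("miR-1", "miRNA", "G1", 8, 15)]
        cat = pool_sites(utrs, sites)
        trios, _ = classify_pairs(cat, class_filter="RBP-miRNA")
        assert all({t.regulator_a[1], t.regulator_b[1]} == {"RBP", "miRNA"}
                   for t in trios)
        assert len(trios) == 2

    def test_symmetric_under_site_label_swap(self):
        utrs = {"G1": make_utr("G1", 100)}
        sites = [rbp_site("RBP1", 5, 15), rbp_site("RBP2", 14, 30)]
        swapped = [rbp_site("RBP2", 5, 15), rbp_site("RBP1", 14, 30)]
        t1, _ = classify_pairs(pool_sites(utrs, sites))
        t2, _ = classify_pairs(pool_sites(utrs, swapped))
        assert [(t.pair_id, t.scenario) for t in t1] == \
               [(t.pair_id, t.scenario) for t in t2]

    def test_pair_summary_counts_genes_per_scenario(self):
        utrs = {g: make_utr(g, 100) for g in ("G1", "G2", "G3")}
        sites = [rbp_site("RBP1", 0, 10, "G1"), rbp_site("RBP2", 5, 15, "G1"),
                 rbp_site("RBP1", 0, 10, "G2"), rbp_site("RBP2", 50, 60, "G2")]
        _, summary = classify_pairs(pool_sites(utrs, sites))
        row = summary.iloc[0]
        assert row["n_genes_overlapping"] == 1
        assert row["n_genes_neighboring"] == 1
        assert row["n_genes_shared"] == 2


class TestFractionSitesOverlapped:
    def test_mutual_overlap_gives_one(self, two_site_catalog):
        _, frac = fraction_sites_overlapped(two_site_catalog)
        assert frac == 1.0

    def test_isolated_sites_give_zero(self):
        utrs = {g: make_utr(g, 100) for g in ("G1", "G2")}
        cat = pool_sites(utrs, [rbp_site("RBP1", 0, 10, "G1"),
                                rbp_site("RBP2", 0, 10, "G2")])
        _, frac = fraction_sites_overlapped(cat)
        assert frac == 0.0

    def test_same_regulator_overlap_does_not_count(self):
        utrs = {"G1": make_utr("G1", 100)}
        cat = pool_sites(utrs, [rbp_site("RBP1", 0, 10), rbp_site("RBP1", 5, 15)],
                         merge_same_regulator=False)
        _, frac = fraction_sites_overlapped(cat)
        assert frac == 0.0

    def test_class_restriction(self):
        utrs = {"G1": make_utr("G1", 100)}
        sites = [rbp_site("RBP1", 0, 10),
                 BindingSite("miR-1", "miRNA", "G1", 5, 12)]
        cat = pool_sites(utrs, sites)
        table, frac_any = fraction_sites_overlapped(cat, by="any")
        assert frac_any == 1.0
        table, frac_mir = fraction_sites_overlapped(cat, by="any-miRNA")
        overlapped = table.set_index("regulator_id")["overlapped"]
        assert bool(overlapped["RBP1"]) and not bool(overlapped["miR-1"])


class TestRandomizeSites:
    def test_forced_overlap_when_sites_cannot_avoid_each_other(self):
        # two length-6 sites on a length-10 UTR always intersect
        utrs = {"G1": make_utr("G1", 10)}
        cat = pool_sites(utrs, [rbp_site("A", 0, 6), rbp_site("B", 4, 10)])
        null = randomize_sites(cat, n_rounds=20, seed=1)
        assert null.null_overlap_fractions.tolist() == [1.0] * 20

    def test_single_regulator_has_no_cross_overlap(self):
        utrs = {"G1": make_utr("G1", 50)}
        cat = pool_sites(utrs, [rbp_site("A", 0, 10)])
        null = randomize_sites(cat, n_rounds=5, seed=1)
        assert null.null_mean == 0.0

    def test_enumerated_two_site_oracle(self):
        # UTR length 10, two length-3 sites: 8x8 equally likely start pairs,
        # overlap iff |i - j| < 3 -> 34/64 by exhaustive enumeration
        starts = range(8)
        hits = sum(abs(i - j) < 3 for i in starts for j in starts)
        assert hits / 64 == 0.53125
        utrs = {"G1": make_utr("G1", 10)}
        cat = pool_sites(utrs, [rbp_site("A", 0, 3), rbp_site("B", 5, 8)])
        null = randomize_sites(cat, n_rounds=400, seed=7)
        se = np.sqrt(0.53125 * (1 - 0.53125) / 400)
        assert abs(null.null_mean - 0.53125) < 3 * se

    def test_round_conserves_counts_lengths_and_genes(self, rng):
        utrs = {g: make_utr(g, 60) for g in ("G1", "G2")}
        sites = [rbp_site("A", 0, 10, "G1"), rbp_site("B", 20, 25, "G1"),
                 rbp_site("A", 5, 35, "G2")]
        cat = pool_sites(utrs, sites)
        placed = randomized_placement(cat, cat.sites, rng)
        key = lambda ss: sorted((s.regulator_id, s.gene_id, s.length) for s in ss)
        assert key(placed) == key(cat.sites)
        for s in placed:
            assert 0 <= s.start and s.end <= cat.utrs[s.gene_id].length

    def test_reproducible_given_seed(self, two_site_catalog):
        a = randomize_sites(two_site_catalog, n_rounds=10, seed=3)
        b = randomize_sites(two_site_catalog, n_rounds=10, seed=3)
        np.testing.assert_array_equal(a.null_overlap_fractions,
                                      b.null_overlap_fractions)

    def test_site_longer_than_utr_rejected(self):
        utrs = {"G1": make_utr("G1", 5)}
        cat = SiteCatalog(utrs=utrs, sites=[rbp_site("A", 0, 5)])
        cat.sites[0] = BindingSite("A", "RBP", "G1", 0, 5)
        # shrink the UTR below the site length
        cat.utrs["G1"] = make_utr("G1", 4)
        with pytest.raises(ValueError, match="longer than"):
            randomize_sites(cat, n_rounds=1, seed=0)

    def test_planted_colocalization_exceeds_null(self):
        # deliberately co-localized sites on long UTRs: observed >> null
        utrs = {f"G{i}": make_utr(f"G{i}", 500) for i in range(20)}
        sites = []
        for i in range(20):
            sites += [rbp_site("A", 100, 120, f"G{i}"),
                      rbp_site("B", 110, 130, f"G{i}")]
        cat = pool_sites(utrs, sites)
        null = randomize_sites(cat, n_rounds=20, seed=5)
        assert null.observed_overlap_fraction == 1.0
        assert null.observed_overlap_fraction > null.null_mean
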
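import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from transinteract import (
    InteractionFit,
    TrioRecord,
    compare_scenarios,
    fisher_enrichment_p,
    fisher_recurrence,
    ks_greater,
    recurrent_pairs,
)
from transinteract.comparison_stats import d_plus_statistic


def make_fit(p, scenario="overlapping", cond="tumor", pair=("A", "B"), gene="G1",
             q=None):
    trio = TrioRecord((pair[0], "RBP"), (pair[1], "RBP"), gene, scenario,
                      1 if scenario == "overlapping" else 0)
    return InteractionFit(trio, cond, 0, 0, 0, 0, 1.0, p, 30, q_a3=q)


class TestKsGreater:
    def test_identical_samples(self):
        c = ks_greater([0.1, 0.5, 0.9], [0.1, 0.5, 0.9], exact=False)
        assert c.d_plus == 0.0
        assert c.p_ks == 1.0

    def test_fully_separated_samples_match_asymptotic_formula(self):
        c = ks_greater([0.1, 0.2], [0.8, 0.9], exact=False)
        assert c.d_plus == 1.0
        assert c.p_ks == pytest.approx(math.exp(-2.0))

    def test_directional_null_gives_large_p(self, rng):
        # x stochastically larger than y: ECDF_x sits below ECDF_y
        x = rng.uniform(0.5, 1.0, 200)
        y = rng.uniform(0.0, 0.5, 200)
        c = ks_greater(x, y, exact=False)
        assert c.d_plus < 0.05
        assert c.p_ks > 0.9

    def test_matches_scipy_one_sided_asymptotic(self, rng):
        # scipy adds a finite-sample (Hodges) correction to the plain
        # exp(-2 d^2 n_e) tail; statistic matches exactly, p to leading order
        for _ in range(10):
            x = rng.random(40)
            y = rng.random(60)
            c = ks_greater(x, y, exact=False)
            ref = stats.ks_2samp(x, y, alternative="greater", method="asymp")
            assert c.d_plus == pytest.approx(ref.statistic, abs=1e-12)
            n_e = len(x) * len(y) / (len(x) + len(y))
            assert c.p_ks == pytest.approx(
                min(1.0, math.exp(-2 * c.d_plus**2 * n_e)), abs=1e-12)
            # scipy's log p is ours plus exactly the Hodges term
            m, n = max(len(x), len(y)), min(len(x), len(y))
            z = math.sqrt(n_e) * c.d_plus
            hodges = -2 * z * (m + 2 * n) / math.sqrt(m * n * (m + n)) / 3.0
            assert math.log(ref.pvalue) == pytest.approx(
                math.log(c.p_ks) + hodges, abs=1e-9)

    def test_exact_permutation_agrees_with_asymptotic_for_small_n(self, rng):
        x = rng.uniform(0, 0.6, 8)
        y = rng.uniform(0.3, 1.0, 9)
        asym = ks_greater(x, y, exact=False)
        perm = ks_greater(x, y, exact=True, n_permutations=20000, seed=1)
        # permutation p is finite-sample; agreement is loose but directional
        assert perm.d_plus == asym.d_plus
        assert abs(perm.p_ks - asym.p_ks) < 0.12

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_greater([], [0.1])

    def test_d_plus_is_ecdf_supremum(self, rng):
        x = rng.random(17)
        y = rng.random(23)
        grid = np.sort(np.concatenate([x, y]))
        brute = max(
            (x <= t).mean() - (y <= t).mean() for t in grid
        )
        assert d_plus_statistic(x, y) == pytest.approx(brute, abs=1e-12)


class TestCompareScenarios:
    def test_three_ordered_comparisons(self):
        fits = (
            [make_fit(p, "overlapping") for p in (0.001, 0.002, 0.01)]
            + [make_fit(p, "neighboring") for p in (0.05, 0.2, 0.4)]
            + [make_fit(p, "independent") for p in (0.5, 0.7, 0.9)]
        )
        comps = compare_scenarios(fits)
        assert [(c.group_x, c.group_y) for c in comps] == [
            ("overlapping", "neighboring"),
            ("overlapping", "independent"),
            ("neighboring", "independent"),
        ]
        assert all(c.available for c in comps)
        assert comps[1].d_plus == 1.0

    def test_empty_group_marked_unavailable(self):
        fits = [make_fit(0.01, "overlapping"), make_fit(0.5, "neighboring")]
        comps = compare_scenarios(fits)
        by_groups = {(c.group_x, c.group_y): c for c in comps}
        assert not by_groups[("overlapping", "independent")].available
        assert by_groups[("overlapping", "neighboring")].available

    def test_degenerate_fits_excluded(self):
        good = make_fit(0.2, "overlapping")
        bad = make_fit(0.0, "overlapping")
        bad.degenerate = True
        comps = compare_scenarios([good, bad, make_fit(0.5, "neighboring")])
        assert comps[0].n_x == 1

    def test_invariant_to_fit_ordering(self, rng):
        fits = [make_fit(p, s) for s in
                ("overlapping", "neighboring", "independent")
                for p in rng.random(10)]
        a = compare_scenarios(fits)
        shuffled = list(fits)
        rng.shuffle(shuffled)
        b = compare_scenarios(shuffled)
        assert [(c.d_plus, c.p_ks) for c in a] == [(c.d_plus, c.p_ks) for c in b]


class TestFisher:
    def test_enumerated_2x2_oracle(self):
        # [[2,1],[1,2]]: P[X>=2] with N=6, K=3, n=3 enumerates to 10/20
        from math import comb

        total = comb(6, 3)
        p_exact = sum(comb(3, k) * comb(3, 3 - k) for k in (2, 3)) / total
        _, p = fisher_enrichment_p([[2, 1], [1, 2]])
        assert p == pytest.approx(p_exact) == pytest.approx(0.5)

    @pytest.mark.parametrize("k", [2, 3, 5])
    def test_most_extreme_table(self, k):
        from math import comb

        _, p = fisher_enrichment_p([[k, 0], [0, k]])
        assert p == pytest.approx(1 / comb(2 * k, k))

    def test_zero_significant_gives_p_one(self):
        _, p = fisher_enrichment_p([[0, 0], [3, 5]])
        assert p == 1.0

    def test_matches_scipy_one_sided(self, rng):
        for _ in range(20):
            a, b, c, d = rng.integers(0, 10, 4)
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            _, p = fisher_enrichment_p([[a, b], [c, d]])
            ref = stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1]
            assert p == pytest.approx(ref, rel=1e-9)


class TestFisherRecurrence:
    def _fits(self):
        fits = []
        # pair (A,B): 3 significant trios of 3; pair (C,D): 0 of 3
        for i, q in enumerate((0.01, 0.02, 0.03)):
            fits.append(make_fit(q / 5, "overlapping", pair=("A", "B"),
                                 gene=f"G{i}", q=q))
        for i, q in enumerate((0.5, 0.6, 0.7)):
            fits.append(make_fit(q / 2, "overlapping", pair=("C", "D"),
                                 gene=f"H{i}", q=q))
        return fits

    def test_enriched_pair_ranks_first(self):
        results = fisher_recurrence(self._fits())
        by_pair = {r.pair_id: r for r in results}
        assert by_pair[("A", "B")].p_fisher < by_pair[("C", "D")].p_fisher
        assert by_pair[("C", "D")].p_fisher == 1.0
        assert by_pair[("A", "B")].table == ((3, 0), (0, 3))

    def test_super_uniform_under_label_permutation(self, rng):
        # permuting significance calls across trios: p-values should not be
        # systematically small (calibration of the one-sided test)
        fits = self._fits()
        ps = []
        for rep in range(200):
            qs = rng.permutation([0.01, 0.02, 0.03, 0.5, 0.6, 0.7])
            permuted = [
                make_fit(0.1, "overlapping",
                         pair=f.trio.pair_id, gene=f.trio.gene_id, q=q)
                for f, q in zip(fits, qs)
            ]
            results = fisher_recurrence(permuted)
            ps.extend(r.p_fisher for r in results)
        assert np.mean(np.asarray(ps) < 0.05) <= 0.05 + 0.03

    def test_recurrent_pairs_across_conditions(self):
        fits = []
        for cond in ("tumor", "normal"):
            for i in range(6):
                fits.append(make_fit(0.001, "overlapping", cond,
                                     pair=("A", "B"), gene=f"G{i}", q=0.001))
            for i in range(6):
                fits.append(make_fit(0.9, "overlapping", cond,
                                     pair=("C", "D"), gene=f"H{i}", q=0.9))
        results = fisher_recurrence(fits)
        rec = recurrent_pairs(results, alpha_q=0.05, min_conditions=2)
        assert rec["regulator_a"].tolist() == ["A"]
        assert rec["n_conditions"].tolist() == [2]
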
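"""Overlap algebra, A/B/C decomposition, randomized nulls, Fisher test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from damidtile import (Interval, PeakSet, decompose_sets, gene_set_fisher,
                       merge_intervals, overlap_peaks, random_peak_null)
from damidtile.arrays import Peak
from helpers import oracle_fisher_two_sided, oracle_overlap_pairs


def peakset(name, triples):
    return PeakSet(name, [
        Peak(Interval(c, s, e, ".", f"{name}_{i}"), 0, float("nan"),
             (s + e) // 2)
        for i, (c, s, e) in enumerate(triples)
    ])


class TestOverlapPeaks:
    def test_one_bp_overlap_counts(self):
        res = overlap_peaks(peakset("x", [("c", 0, 100)]),
                            peakset("y", [("c", 99, 200)]))
        assert res.pairs == [(0, 0)]

    def test_half_open_touching_does_not_count(self):
        res = overlap_peaks(peakset("x", [("c", 0, 100)]),
                            peakset("y", [("c", 100, 200)]))
        assert res.pairs == []

    def test_min_bp_threshold(self):
        x = peakset("x", [("c", 0, 100)])
        y = peakset("y", [("c", 95, 200)])
        assert overlap_peaks(x, y, min_bp=5).pairs == [(0, 0)]
        assert overlap_peaks(x, y, min_bp=6).pairs == []

    def test_many_to_many(self):
        x = peakset("x", [("c", 0, 1000)])
        y = peakset("y", [("c", 10, 20), ("c", 500, 600), ("c", 999, 2000)])
        res = overlap_peaks(x, y)
        assert sorted(res.pairs) == [(0, 0), (0, 1), (0, 2)]

    def test_matches_brute_force_oracle(self, rng):
        def random_set(n):
            trips = []
            for _ in range(n):
                c = f"chr{rng.integers(1, 4)}"
                s = int(rng.integers(0, 100_000))
                trips.append((c, s, s + int(rng.integers(1, 2000))))
            return trips
        X, Y = random_set(500), random_set(500)
        res = overlap_peaks(peakset("x", X), peakset("y", Y))
        assert sorted(res.pairs) == sorted(oracle_overlap_pairs(X, Y))
        # symmetry: flag counts agree with the pair list
        assert res.x_overlaps.sum() == len({i for i, _ in res.pairs})
        assert res.y_overlaps.sum() == len({j for _, j in res.pairs})

    def test_disjoint_namespaces_error(self):
        with pytest.raises(ValueError, match="namespace"):
            overlap_peaks(peakset("x", [("chr1", 0, 10)]),
                          peakset("y", [("scaffold9", 0, 10)]))


class TestDecomposeSets:
    def test_identical_sets(self):
        s = peakset("x", [("c", 0, 100), ("c", 500, 700)])
        d = decompose_sets(s, s)
        assert len(d.A) == 0 and len(d.C) == 0
        assert len(d.B_wt) == 2 and len(d.B_mut) == 2

    def test_disjoint_sets(self):
        wt = peakset("wt", [("c", 0, 100)])
        mut = peakset("mut", [("c", 500, 700), ("c", 900, 1000)])
        d = decompose_sets(wt, mut)
        assert len(d.A) == 1 and len(d.B_wt) == 0
        assert len(d.B_mut) == 0 and len(d.C) == 2

    def test_b_membership_counts_once_per_side(self):
        wt = peakset("wt", [("c", 0, 1000)])
        mut = peakset("mut", [("c", 10, 20), ("c", 100, 200)])
        d = decompose_sets(wt, mut)
        assert len(d.B_wt) == 1 and len(d.B_mut) == 2

    def test_summary_reports_both_percentages(self):
        wt = peakset("wt", [("c", 0, 100), ("c", 200, 300), ("c", 400, 500),
                            ("c", 600, 700)])
        mut = peakset("mut", [("c", 50, 150), ("c", 1000, 1100)])
        s = decompose_sets(wt, mut).summary()
        assert s["B_pct_of_wt"] == pytest.approx(25.0)
        assert s["B_pct_of_mut"] == pytest.approx(50.0)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(data=st.data())
    def test_conservation_property(self, data):
        def rand_set(name):
            n = data.draw(st.integers(0, 20))
            trips = []
            for k in range(n):
                s = data.draw(st.integers(0, 5000))
                trips.append(("c", s, s + data.draw(st.integers(1, 500))))
            return peakset(name, trips)
        wt, mut = rand_set("wt"), rand_set("mut")
        d = decompose_sets(wt, mut)
        assert len(d.A) + len(d.B_wt) == len(wt)
        assert len(d.B_mut) + len(d.C) == len(mut)


class TestMergeIntervals:
    def test_gap_merging(self):
        ivs = [Interval("c", 0, 25), Interval("c", 35, 60),
               Interval("c", 1000, 1025)]
        assert len(merge_intervals(ivs)) == 3
        blocks = merge_intervals(ivs, gap=10)
        assert [(b.start, b.end) for b in blocks] == [(0, 60), (1000, 1025)]


class TestRandomPeakNull:
    def territory(self):
        return [Interval("c", 0, 500_000)]

    def test_query_equals_reference(self, rng):
        starts = np.sort(rng.choice(490_000, size=50, replace=False))
        ps = peakset("r", [("c", int(s), int(s) + 800) for s in starts])
        null = random_peak_null(ps, ps, self.territory(), n_iter=99, seed=1)
        assert null.observed_fraction == 1.0
        assert null.p_value == pytest.approx(1 / 100)

    def test_infeasible_territory_error(self):
        ps = peakset("r", [("c", 0, 5000)])
        with pytest.raises(ValueError, match="territory"):
            random_peak_null(ps, ps, [Interval("c", 0, 100)], n_iter=10)

    def test_null_draws_respect_lengths_and_territory(self, rng):
        from damidtile.peaksets import _sample_random_intervals
        territory = [Interval("c", 100, 5000), Interval("d", 0, 3000)]
        lengths = np.array([500, 1000, 2500])
        for _ in range(50):
            drawn = _sample_random_intervals(lengths, territory, rng)
            for iv, L in zip(drawn, lengths):
                assert len(iv) == L
                assert any(b.chrom == iv.chrom and b.start <= iv.start
                           and iv.end <= b.end for b in territory)
        # length 3500 only fits in the first block
        assert all(_sample_random_intervals(np.array([3500]), territory,
                                            rng)[0].chrom == "c"
                   for _ in range(10))

    def test_independent_sets_give_central_observed(self, rng):
        # observed statistic should fall inside the central 95% of its own
        # null in the large majority of replicate worlds
        hits = 0
        n_rep = 40
        for rep in range(n_rep):
            r = np.random.default_rng(1000 + rep)
            ref = peakset("ref", [("c", int(s), int(s) + 600)
                                  for s in np.sort(r.choice(490_000, 40,
                                                            replace=False))])
            qry = peakset("q", [("c", int(s), int(s) + 600)
                                for s in np.sort(r.choice(490_000, 40,
                                                          replace=False))])
            null = random_peak_null(ref, qry, self.territory(), n_iter=199,
                                    seed=rep)
            lo, hi = np.quantile(null.null_fractions, [0.025, 0.975])
            hits += lo <= null.observed_fraction <= hi
        assert hits >= 0.9 * n_rep


class TestGeneSetFisher:
    def test_symmetric_table(self):
        universe = {f"g{i}" for i in range(40)}
        A = {f"g{i}" for i in range(20)}
        B = {f"g{i}" for i in range(10, 30)}
        res = gene_set_fisher(A, B, universe)
        assert res["table"] == (10, 10, 10, 10)
        assert res["odds_ratio"] == pytest.approx(1.0)
        assert res["p_two_sided"] == pytest.approx(1.0)

    def test_no_overlap_haldane_branch(self):
        universe = {f"g{i}" for i in range(100)}
        A = {f"g{i}" for i in range(10)}
        B = {f"g{i}" for i in range(10, 20)}
        res = gene_set_fisher(A, B, universe)
        assert res["overlap_count"] == 0
        assert res["odds_ratio"] < 1
        assert res["p_two_sided"] <= 1.0

    def test_matches_enumeration_oracle(self):
        universe = {f"g{i}" for i in range(16)}
        A = {f"g{i}" for i in range(10)}           # a+b = 10
        B = {f"g{i}" for i in range(8, 9)} | {f"g{i}" for i in range(10, 15)}
        res = gene_set_fisher(A, B, universe)
        a, b, c, d = res["table"]
        assert res["p_two_sided"] == pytest.approx(
            oracle_fisher_two_sided(a, b, c, d), rel=1e-9)

    def test_empty_universe_and_subset_errors(self):
        with pytest.raises(ValueError, match="universe"):
            gene_set_fisher({"a"}, {"b"}, set())
        with pytest.raises(ValueError, match="subset"):
            gene_set_fisher({"a"}, {"b"}, {"b"})
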
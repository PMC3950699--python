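"""Pair enumeration, shuffling null, empirical p-values, FDR and calls."""

import itertools

import numpy as np
import pandas as pd
import pytest

from comotif.colocalization import (
    PairEngine,
    PivotResult,
    bh_fdr,
    call_pairs,
    candidate_filter,
    edge_swap_randomize,
    empirical_pvalues,
    enumerate_pairs,
    enumerate_stratum_assignments,
    shuffle_identities,
    stage_enrichment_ratio,
    weighted_histogram,
)

from conftest import sites_frame


class TestEnumeratePairs:
    def test_nearest_per_side_rule(self):
        # three same-motif sites at gaps 10, 250, 800 on the right: nearest only
        sites = sites_frame(
            [("P", "c", 1000, 1008),
             ("B", "c", 1018, 1026), ("B", "c", 1258, 1266), ("B", "c", 1808, 1816)]
        )
        pairs = enumerate_pairs(sites, "P")
        assert len(pairs) == 1 and pairs.iloc[0]["distance"] == 10

    def test_one_per_side(self):
        sites = sites_frame(
            [("P", "c", 1000, 1008), ("B", "c", 900, 908), ("B", "c", 1100, 1108)]
        )
        pairs = enumerate_pairs(sites, "P")
        assert sorted(pairs["side"]) == ["left", "right"]
        assert sorted(pairs["distance"]) == [92, 92]

    def test_homotypic_excluded(self):
        sites = sites_frame([("P", "c", 1000, 1008), ("P", "c", 1020, 1028)])
        assert len(enumerate_pairs(sites, "P")) == 0

    def test_overlap_distance_zero(self):
        sites = sites_frame([("P", "c", 1000, 1008), ("B", "c", 1004, 1012)])
        assert enumerate_pairs(sites, "P")["distance"].tolist() == [0]

    def test_weight_is_min_percentile(self):
        sites = sites_frame([("P", "c", 1000, 1008, 0.7), ("B", "c", 1020, 1028, 0.9)])
        assert enumerate_pairs(sites, "P")["weight"].tolist() == [0.7]

    def test_matches_quadratic_oracle(self, rng):
        rows = []
        for m in ("P", "B", "C", "D"):
            for s in rng.integers(0, 5000, 12):
                rows.append((m, "c", int(s), int(s) + 8, round(float(rng.random()), 2)))
        sites = sites_frame(rows)
        got = enumerate_pairs(sites, "P", max_dist=1000)
        got_keys = sorted(zip(got["pivot_start"], got["other_motif"], got["side"], got["distance"]))

        piv = sites[sites.motif_id == "P"]
        oth = sites[sites.motif_id != "P"]
        expect = []
        for p in piv.itertuples():
            for m in ("B", "C", "D"):
                for side in ("left", "right"):
                    cands = []
                    for o in oth[oth.motif_id == m].itertuples():
                        gap = max(0, max(o.start - p.end, p.start - o.end))
                        o_side = "left" if (o.start + o.end) / 2 < (p.start + p.end) / 2 else "right"
                        if o_side == side and gap <= 1000:
                            cands.append((gap, o.start))
                    if cands:
                        expect.append((p.start, m, side, min(cands)[0]))
        assert got_keys == sorted(expect)


class TestWeightedHistogram:
    def test_empty(self):
        assert weighted_histogram([], []).tolist() == [0] * 10

    def test_additive_first_bin(self):
        h = weighted_histogram([50, 70], [0.8, 0.9])
        assert h[0] == pytest.approx(1.7) and h[1:].sum() == 0

    def test_matches_direct_sum(self, rng):
        d = rng.integers(0, 1100, 200)
        w = rng.random(200)
        h = weighted_histogram(d, w)
        for b in range(10):
            assert h[b] == pytest.approx(w[(d >= b * 100) & (d < (b + 1) * 100)].sum())


class TestShuffleIdentities:
    def test_singleton_strata_identity(self, rng):
        sites = sites_frame([("A", "c", 10, 18), ("B", "c", 50, 58), ("C", "c", 90, 98)])
        comp = {"A": 0, "B": 1, "C": 2}
        out = shuffle_identities(sites, comp, np.random.default_rng(0), pivot_motif="P")
        assert out["motif_id"].tolist() == ["A", "B", "C"]

    def test_per_stratum_counts_conserved(self, rng):
        rows = []
        for m, comp_label in [("A", 0), ("B", 0), ("C", 1), ("D", 1)]:
            for chrom in ("c1", "c2"):
                for s in rng.integers(0, 5000, 10):
                    rows.append((m, chrom, int(s), int(s) + 8))
        sites = sites_frame(rows)
        comp = {"A": 0, "B": 0, "C": 1, "D": 1}
        for seed in range(5):
            out = shuffle_identities(sites, comp, np.random.default_rng(seed), pivot_motif="A")
            for chrom in ("c1", "c2"):
                for label in (0, 1):
                    keys_in = [m for m, c in zip(sites.motif_id, sites.chrom)
                               if c == chrom and comp[m] == label and m != "A"]
                    keys_out = [m for m, c in zip(out.motif_id, out.chrom)
                                if c == chrom and comp[m] == label and m != "A"]
                    assert sorted(keys_in) == sorted(keys_out)

    def test_pivot_sites_frozen(self, rng):
        sites = sites_frame([("A", "c", i * 100, i * 100 + 8) for i in range(5)]
                            + [("B", "c", i * 100 + 50, i * 100 + 58) for i in range(5)])
        comp = {"A": 0, "B": 0}
        out = shuffle_identities(sites, comp, np.random.default_rng(1), pivot_motif="A")
        pd.testing.assert_frame_equal(out[out.start % 100 == 0], sites[sites.start % 100 == 0])

    def test_uniform_over_permutations(self):
        # one stratum of 3 distinguishable records (labels B, C, D): each of
        # the 6 assignments should appear with frequency 1/6
        sites = sites_frame([("B", "c", 0, 8), ("C", "c", 100, 108), ("D", "c", 200, 208)])
        comp = {"B": 0, "C": 0, "D": 0}
        rng = np.random.default_rng(123)
        counts = {}
        n = 6000
        for _ in range(n):
            out = shuffle_identities(sites, comp, rng)
            counts[tuple(out["motif_id"])] = counts.get(tuple(out["motif_id"]), 0) + 1
        assert len(counts) == 6
        p = 1 / 6
        bound = 3 * np.sqrt(p * (1 - p) / n)
        for k, v in counts.items():
            assert abs(v / n - p) < bound + 1e-9, (k, v / n)


class TestEmpiricalP:
    def test_real_below_all_nulls(self):
        assert empirical_pvalues(np.array([0.1]), np.array([[1.0], [2.0]]))[0] == 1.0

    def test_real_above_all_nulls(self):
        assert empirical_pvalues(np.array([5.0]), np.array([[1.0], [2.0]]))[0] == 0.0

    def test_ties_count_as_extreme(self):
        assert empirical_pvalues(np.array([2.0]), np.array([[2.0], [1.0]]))[0] == 0.5


class TestCandidateFilter:
    def test_both_sides_rule(self):
        masses = np.array([200.0])
        assert not candidate_filter(np.array([[1.5]]), masses, 100.0)[0, 0]
        assert candidate_filter(np.array([[2.5]]), masses, 100.0)[0, 0]

    def test_matches_inequality_oracle(self, rng):
        real = rng.random((6, 10)) * 5
        masses = rng.random(6) * 300
        pm = 150.0
        got = candidate_filter(real, masses, pm)
        for i in range(6):
            for b in range(10):
                assert got[i, b] == (real[i, b] >= 0.01 * pm and real[i, b] >= 0.01 * masses[i])


class TestBH:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.37]), [0.37])


def _pivot_result(pivot, motifs, first_bin, pvals, mass=100.0):
    M = len(motifs)
    real = np.zeros((M, 10))
    pv = np.ones((M, 10))
    for m, v in first_bin.items():
        real[motifs.index(m), 0] = v
    for m, v in pvals.items():
        pv[motifs.index(m), 0] = v
    elig = real >= 0.01
    elig[motifs.index(pivot), :] = False
    return PivotResult(
        pivot=pivot, motifs=motifs, real=real,
        null_mean=np.full((M, 10), 1.0), null_sd=np.zeros((M, 10)),
        pvalues=pv, eligible=elig, mass={m: mass for m in motifs},
    )


class TestCallPairs:
    MOTIFS = ["A", "B"]

    def _results(self, p_ab, p_ba, count=20.0):
        return {
            "s1": {
                "A": _pivot_result("A", self.MOTIFS, {"B": count}, {"B": p_ab}),
                "B": _pivot_result("B", self.MOTIFS, {"A": count}, {"A": p_ba}),
            }
        }

    def test_reciprocal_pair_called(self):
        table = call_pairs(self._results(0.001, 0.001))
        assert table.iloc[0]["called"]

    def test_one_sided_not_called(self):
        table = call_pairs(self._results(0.001, 0.8))
        assert not table.iloc[0]["called"]

    def test_count_floor(self):
        table = call_pairs(self._results(0.001, 0.001, count=9.5))
        assert not table.iloc[0]["called"]
        assert table.iloc[0]["reciprocal"]

    def test_symmetric_in_pair_order(self):
        t = call_pairs(self._results(0.001, 0.001))
        assert (t.iloc[0]["motif_a"], t.iloc[0]["motif_b"]) == ("A", "B")


class TestStageEnrichment:
    def test_flat_ratios(self):
        ratios, centered = stage_enrichment_ratio({"a": 5.0, "b": 5.0}, {"a": 5.0, "b": 5.0})
        assert ratios == {"a": 1.0, "b": 1.0} and centered == {"a": 1.0, "b": 1.0}

    def test_centering_arithmetic(self):
        real = {s: v for s, v in zip("abcde", [2.0, 1, 1, 1, 1])}
        null = {s: 1.0 for s in "abcde"}
        ratios, centered = stage_enrichment_ratio(real, null)
        assert centered["a"] == pytest.approx(5 / 3)
        for s in "bcde":
            assert centered[s] == pytest.approx(5 / 6)

    def test_zero_null_excluded_with_warning(self):
        with pytest.warns(UserWarning):
            ratios, _ = stage_enrichment_ratio({"a": 1.0, "b": 1.0}, {"a": 0.0, "b": 2.0})
        assert list(ratios) == ["b"]


class TestEdgeSwap:
    def test_degree_sequence_preserved(self, rng):
        edges = [(f"n{i}", f"n{(i * 3 + 1) % 11}") for i in range(11)]
        edges = [e for e in edges if e[0] != e[1]]
        out = edge_swap_randomize(edges, 50, np.random.default_rng(0))
        deg_in = pd.Series([n for e in edges for n in e]).value_counts()
        deg_out = pd.Series([n for e in out for n in e]).value_counts()
        pd.testing.assert_series_equal(deg_in.sort_index(), deg_out.sort_index())

    def test_no_self_loops_or_duplicates(self, rng):
        edges = [(i, j) for i in range(6) for j in range(i + 1, 6)][:10]
        out = edge_swap_randomize(edges, 100, np.random.default_rng(1))
        norm = [tuple(sorted(e)) for e in out]
        assert len(set(norm)) == len(norm)
        assert all(a != b for a, b in out)

    def test_four_cycle_reaches_both_states(self):
        edges = [(0, 1), (1, 2), (2, 3), (3, 0)]
        seen = set()
        for seed in range(40):
            out = edge_swap_randomize(edges, 1, np.random.default_rng(seed))
            seen.add(frozenset(tuple(sorted(e)) for e in out))
        assert len(seen) == 2  # the 4-cycle and the two-parallel-pairs graph

    def test_star_returned_with_degrees_intact(self):
        edges = [("hub", f"leaf{i}") for i in range(5)]
        out = edge_swap_randomize(edges, 10, np.random.default_rng(2))
        assert sorted(out) == sorted(edges)  # no legal swap exists

    def test_small_network_unchanged(self):
        assert edge_swap_randomize([("a", "b")], 5, np.random.default_rng(0)) == [("a", "b")]


class TestExactEnumeration:
    def test_engine_matches_exhaustive_enumeration(self):
        # 2 pivot sites, 4 shuffleable sites in one stratum
        sites = sites_frame(
            [("P", "c", 1000, 1008, 0.9), ("P", "c", 3000, 3008, 0.8),
             ("B", "c", 1030, 1038, 0.7), ("C", "c", 1200, 1208, 0.95),
             ("B", "c", 3050, 3058, 0.85), ("C", "c", 4500, 4508, 0.6)]
        )
        eng = PairEngine(sites, "P")
        strata = eng.strata({"B": 0, "C": 0, "P": 0})
        assert sum(len(s) for s in strata) == 4
        real = eng.histogram()
        nulls = np.stack([eng.histogram(lab) for lab in
                          enumerate_stratum_assignments(eng.labels0, strata)])
        pv = empirical_pvalues(real, nulls)

        # oracle: recompute each assignment's first-bin count from scratch
        oth = sites[sites.motif_id != "P"].reset_index(drop=True)
        piv = sites[sites.motif_id == "P"].reset_index(drop=True)
        perms = sorted(set(itertools.permutations(oth["motif_id"])))
        b_idx = eng.motif_index["B"]
        exact = []
        for perm in perms:
            count = 0.0
            for p in piv.itertuples():
                for side in ("l", "r"):
                    best = None
                    for o, lab in zip(oth.itertuples(), perm):
                        if lab != "B":
                            continue
                        gap = max(0, max(o.start - p.end, p.start - o.end))
                        o_side = "l" if (o.start + o.end) / 2 < (p.start + p.end) / 2 else "r"
                        if o_side == side and gap <= 1000:
                            if best is None or gap < best[0]:
                                best = (gap, min(p.percentile, o.percentile))
                    if best and best[0] < 100:
                        count += best[1]
            exact.append(count)
        exact = np.array(exact)
        expect_p = (exact >= exact[perms.index(tuple(oth["motif_id"]))]).mean()
        # engine null enumerated over distinct label arrays; compare p for B bin 0
        assert pv[b_idx, 0] == pytest.approx(expect_p, abs=1e-12)


class TestDeterminism:
    def test_null_histograms_reproducible(self, rng):
        rows = []
        for m in ("P", "B", "C", "D"):
            for s in rng.integers(0, 8000, 15):
                rows.append((m, "c", int(s), int(s) + 8))
        sites = sites_frame(rows)
        comp = {m: 0 for m in "PBCD"}
        eng = PairEngine(sites, "P")
        strata = eng.strata(comp)
        n1 = eng.null_histograms(strata, np.random.default_rng(9), 25)
        n2 = eng.null_histograms(strata, np.random.default_rng(9), 25)
        np.testing.assert_array_equal(n1, n2)
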
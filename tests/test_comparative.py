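import numpy as np
import pandas as pd
import pytest

from longmeth import comparative as cmp
from oracles import fisher_one_sided, hypergeom_tail, signed_rank_two_sided


def dmr_set(label, members, universe=100, direction="both"):
    return cmp.DMRSet(
        label=label, universe_size=universe, members=frozenset(members),
        direction=direction,
    )


class TestOverlapFisher:
    def test_disjoint_sets_no_enrichment(self):
        a = dmr_set("a", range(10), universe=10_000)
        b = dmr_set("b", range(100, 110), universe=10_000)
        inter, _, p = cmp.overlap_fisher(a, b)
        assert inter == 0
        assert p > 0.99

    def test_matches_hypergeometric_enumeration(self):
        a = dmr_set("a", range(10))
        b = dmr_set("b", list(range(5)) + list(range(50, 55)))
        inter, _, p = cmp.overlap_fisher(a, b)
        assert inter == 5
        assert p == pytest.approx(hypergeom_tail(5, 100, 10, 10), rel=1e-10)

    def test_subset_of_full_universe_degenerate(self):
        a = dmr_set("a", range(10))
        b = dmr_set("b", range(100))  # b == universe
        _, _, p = cmp.overlap_fisher(a, b)
        assert p == pytest.approx(1.0)

    def test_mismatched_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            cmp.overlap_fisher(dmr_set("a", [1]), dmr_set("b", [1], universe=50))

    def test_random_instances_match_enumeration(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            n = int(rng.integers(10, 200))
            ka, kb = int(rng.integers(0, n + 1)), int(rng.integers(0, n + 1))
            ids = rng.permutation(n)
            a = dmr_set("a", ids[:ka].tolist(), universe=n)
            b = dmr_set("b", rng.permutation(n)[:kb].tolist(), universe=n)
            inter, _, p = cmp.overlap_fisher(a, b)
            assert p == pytest.approx(
                hypergeom_tail(inter, n, ka, kb), rel=1e-9, abs=1e-300
            )


class TestGenesWithDmrs:
    def _dmrs(self, spans_deltas):
        rows = []
        for i, (start, end, delta) in enumerate(spans_deltas):
            rows.append((i, "chr1", start, end, delta, True))
        return pd.DataFrame(
            rows, columns=["window_id", "chrom", "start", "end", "delta_pp", "is_dmr"]
        )

    def _genes(self):
        return pd.DataFrame(
            [("g1", "chr1", 1000, 5000, "+", 1000)],
            columns=["gene_id", "chrom", "start", "end", "strand", "tss"],
        )

    def test_two_concordant_dmrs_retained(self):
        out = cmp.genes_with_dmrs(self._dmrs([(1200, 1800, 15), (2000, 2600, 20)]), self._genes())
        row = out.iloc[0]
        assert row["avg_delta_pp"] == pytest.approx(17.5)
        assert row["retained"] and row["direction"] == "hyper"

    def test_mixed_directions_cancel_and_drop(self):
        out = cmp.genes_with_dmrs(self._dmrs([(1200, 1800, 15), (2000, 2600, -15)]), self._genes())
        assert out.iloc[0]["avg_delta_pp"] == pytest.approx(0.0)
        assert not out.iloc[0]["retained"]

    def test_single_dmr_not_enough(self):
        out = cmp.genes_with_dmrs(self._dmrs([(1200, 1800, 30)]), self._genes())
        assert not out.iloc[0]["retained"]

    def test_overlap_needs_one_bp(self):
        # DMR ending exactly at gene start (half-open) does not overlap
        out = cmp.genes_with_dmrs(self._dmrs([(500, 1000, 30), (500, 1001, 30)]), self._genes())
        assert out.iloc[0]["n_dmrs"] == 1

    def test_zero_delta_dmr_cannot_flip_direction(self):
        base = self._dmrs([(1200, 1800, 15), (2000, 2600, 20)])
        with_zero = self._dmrs([(1200, 1800, 15), (2000, 2600, 20), (3000, 3200, 0)])
        a = cmp.genes_with_dmrs(base, self._genes())
        b = cmp.genes_with_dmrs(with_zero, self._genes())
        assert a.iloc[0]["direction"] == b.iloc[0]["direction"] == "hyper"


class TestQuadrantAssociation:
    def test_fully_concordant_matches_enumeration(self):
        ids = [f"w{i}" for i in range(40)]
        a = pd.Series([1.0] * 20 + [-1.0] * 20, index=ids)
        b = pd.Series([2.0] * 20 + [-3.0] * 20, index=ids)
        table, p = cmp.quadrant_association(a, b)
        assert table.values.tolist() == [[20, 0], [0, 20]]
        assert p == pytest.approx(hypergeom_tail(20, 40, 20, 20), rel=1e-9)
        assert p == pytest.approx(7.3e-12, rel=0.01)

    def test_independent_signs_uncalibrated_p(self):
        rng = np.random.default_rng(5)
        ps = []
        for _ in range(200):
            ids = range(60)
            a = pd.Series(rng.choice([-1.0, 1.0], 60), index=ids)
            b = pd.Series(rng.choice([-1.0, 1.0], 60), index=ids)
            ps.append(cmp.quadrant_association(a, b)[1])
        # under independence the one-sided p is super-uniform: moderate mass
        # at small values, most of it near 1
        assert np.mean(np.array(ps) < 0.05) < 0.1
        assert np.median(ps) > 0.3

    def test_all_zero_other_axis_rejected(self):
        a = pd.Series([1.0, -1.0], index=["w1", "w2"])
        b = pd.Series([0.0, 0.0], index=["w1", "w2"])
        with pytest.raises(ValueError, match="zero deltas"):
            cmp.quadrant_association(a, b)


class TestConsensus:
    def test_window_in_two_of_three_sets(self):
        sets = [
            dmr_set("a", [1, 2], direction="hyper"),
            dmr_set("b", [2, 3], direction="hyper"),
            dmr_set("c", [4], direction="hyper"),
        ]
        cons = cmp.consensus_dmrs(sets, min_sets=2, direction="hyper")
        assert cons.members == {2}

    def test_opposite_directions_never_merge(self):
        sets = [
            dmr_set("a", [1], direction="hyper"),
            dmr_set("b", [1], direction="hypo"),
        ]
        assert cmp.consensus_dmrs(sets, 2, "hyper").members == frozenset()
        assert cmp.consensus_dmrs(sets, 2, "hypo").members == frozenset()

    def test_min_sets_three(self):
        sets = [dmr_set(l, [7], direction="hyper") for l in "abc"]
        assert cmp.consensus_dmrs(sets, 3, "hyper").members == {7}

    def test_min_sets_exceeding_inputs_rejected(self):
        with pytest.raises(ValueError, match="min_sets"):
            cmp.consensus_dmrs([dmr_set("a", [1], direction="hyper")], 2, "hyper")

    def test_pure_set_algebra_against_bruteforce(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            sets = [
                dmr_set(str(i), rng.choice(50, rng.integers(0, 30), replace=False).tolist(),
                        universe=50, direction="hyper")
                for i in range(4)
            ]
            for min_sets in (2, 3, 4):
                cons = cmp.consensus_dmrs(sets, min_sets, "hyper")
                brute = {
                    w for w in range(50)
                    if sum(w in s.members for s in sets) >= min_sets
                }
                assert cons.members == brute
                # order independence
                shuffled = cmp.consensus_dmrs(sets[::-1], min_sets, "hyper")
                assert shuffled.members == cons.members


class TestMarkerSelection:
    def _spans(self, n=30):
        return pd.DataFrame(
            {
                "window_id": range(n),
                "chrom": "chr1",
                "start": np.arange(n) * 1000,
                "end": np.arange(n) * 1000 + 900,
            }
        )

    def test_intersection_minus_age_consensus(self):
        hyper = [dmr_set(l, range(9), universe=30, direction="hyper") for l in "abc"]
        age = dmr_set("age", [0, 1, 2, 3, 4], universe=30, direction="hypo")
        markers = cmp.select_marker_regions(hyper, age, window_spans=self._spans())
        assert markers == {5, 6, 7, 8}

    def test_empty_intersection(self):
        hyper = [
            dmr_set("a", [1], universe=30, direction="hyper"),
            dmr_set("b", [2], universe=30, direction="hyper"),
        ]
        assert cmp.select_marker_regions(hyper) == frozenset()

    def test_no_age_consensus_returns_full_intersection(self):
        hyper = [dmr_set(l, [3, 4], universe=30, direction="hyper") for l in "ab"]
        assert cmp.select_marker_regions(hyper) == {3, 4}

    def test_genomic_overlap_excludes_touching_windows(self):
        # overlapping-window universes: age window 1 spans [1000,1900) which
        # genomically intersects nothing of window 3 [3000,3900)
        hyper = [dmr_set(l, [3], universe=30, direction="hyper") for l in "ab"]
        age = dmr_set("age", [1], universe=30, direction="hypo")
        assert cmp.select_marker_regions(hyper, age, self._spans()) == {3}


class TestRefineMarkerRegion:
    def test_densest_stretch_chosen(self):
        cpgs = np.concatenate([np.arange(100, 110), np.arange(2000, 2200, 4)])
        s, e, whole = cmp.refine_marker_region("chr1", 0, 4000, cpgs, width=500)
        assert not whole
        assert s >= 1500 and e <= 2600  # covers the dense stretch

    def test_uniform_density_leftmost_of_maximal_starts(self):
        cpgs = np.arange(100, 4000, 10)
        s, _, _ = cmp.refine_marker_region("chr1", 0, 4000, cpgs, width=500)
        # brute force: CpG count per candidate start; pick leftmost maximum
        pos0 = cpgs - 1
        counts = [((pos0 >= c) & (pos0 < c + 500)).sum() for c in range(0, 3501)]
        assert s == int(np.argmax(counts))  # leftmost among ties

    def test_short_region_returned_whole(self):
        s, e, whole = cmp.refine_marker_region("chr1", 100, 500, np.array([200]), width=500)
        assert (s, e, whole) == (100, 500, True)


class TestPairedWilcoxon:
    def test_concerted_shift_minimal_exact_p(self):
        res = cmp.paired_wilcoxon_cpgs(np.full(20, 85.0), np.full(20, 80.0))
        assert res["n"] == 20
        assert res["p"] == pytest.approx(2 / 2**20, rel=1e-9)
        assert res["median_delta"] == pytest.approx(5.0)

    def test_no_informative_pairs_flagged(self):
        res = cmp.paired_wilcoxon_cpgs(np.full(5, 80.0), np.full(5, 80.0))
        assert res["n"] == 0 and np.isnan(res["p"]) and res["small_n"]

    def test_symmetric_differences_null(self):
        treated = np.array([81.0, 79.0, 82.0, 78.0])
        control = np.array([80.0, 80.0, 80.0, 80.0])
        res = cmp.paired_wilcoxon_cpgs(treated, control)
        assert res["p"] > 0.6
        assert res["small_n"]

    def test_matches_exact_enumeration_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            n = int(rng.integers(6, 20))
            diffs = rng.normal(1.0, 2.0, size=n)
            res = cmp.paired_wilcoxon_cpgs(80 + diffs, np.full(n, 80.0))
            assert res["p"] == pytest.approx(signed_rank_two_sided(diffs), rel=1e-9)
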
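"""Marker rankings, attention correlation, enrichment and annotation."""

import math

import numpy as np
import pytest

from cellattn import (
    annotate_clusters,
    attention_correlation,
    cluster_markers,
    enrich,
    global_markers,
)


class TestGlobalMarkers:
    def test_hand_mean_and_sort(self):
        a = np.array([[0.5, 0.3, 0.2], [0.1, 0.6, 0.3]])
        ranking = global_markers(a, ["g1", "g2", "g3"])
        assert ranking.genes == ["g2", "g1", "g3"]
        np.testing.assert_allclose(ranking.scores, [0.45, 0.3, 0.25])

    def test_uniform_attention_ties_break_by_gene_index(self):
        a = np.full((3, 4), 0.25)
        ranking = global_markers(a, ["d", "c", "b", "a"])
        assert ranking.genes == ["d", "c", "b", "a"]

    def test_single_cell_ranking_is_its_sorted_row(self):
        a = np.array([[0.1, 0.7, 0.2]])
        ranking = global_markers(a, ["x", "y", "z"])
        assert ranking.genes == ["y", "z", "x"]

    def test_invariant_to_cell_permutation(self):
        rng = np.random.default_rng(0)
        raw = rng.random((10, 6))
        a = raw / raw.sum(axis=1, keepdims=True)
        names = list("abcdef")
        r1 = global_markers(a, names)
        r2 = global_markers(a[rng.permutation(10)], names)
        assert r1.genes == r2.genes


class TestClusterMarkers:
    def test_single_class_attention_statistic_reduces_to_global(self):
        rng = np.random.default_rng(1)
        raw = rng.random((8, 5))
        a = raw / raw.sum(axis=1, keepdims=True)
        names = list("abcde")
        per = cluster_markers(a, ["k"] * 8, names, top_n=3, statistic="attention")
        assert per["k"].genes == global_markers(a, names).genes[:3]

    def test_single_cell_class_is_its_row(self):
        a = np.array([[0.6, 0.3, 0.1], [0.1, 0.2, 0.7]])
        per = cluster_markers(a, ["p", "q"], ["x", "y", "z"], top_n=2, statistic="attention")
        assert per["q"].genes == ["z", "y"]

    def test_top_n_too_large_raises(self):
        a = np.full((2, 3), 1 / 3)
        with pytest.raises(ValueError, match="top_n"):
            cluster_markers(a, ["a", "b"], ["x", "y", "z"], top_n=4)

    def test_gene_score_statistic_requires_counts(self):
        a = np.full((2, 3), 1 / 3)
        with pytest.raises(ValueError, match="counts"):
            cluster_markers(a, ["a", "b"], list("xyz"), top_n=2, statistic="gene_score")

    def test_recovers_planted_markers(self, small_trained, small_attention):
        ds, _, _ = small_trained
        per = cluster_markers(
            small_attention,
            ds.labels,
            ds.matrix.gene_names,
            top_n=8,
            counts=ds.matrix.counts,
        )
        precisions = [
            len(set(per[t].genes) & set(ds.markers[t])) / 8 for t in ds.markers
        ]
        assert np.mean(precisions) >= 0.8

    def test_invariant_to_within_class_permutation(self):
        rng = np.random.default_rng(2)
        raw = rng.random((10, 4))
        a = raw / raw.sum(axis=1, keepdims=True)
        labels = np.array(["u"] * 5 + ["v"] * 5)
        perm = np.concatenate([rng.permutation(5), 5 + rng.permutation(5)])
        r1 = cluster_markers(a, labels, list("wxyz"), top_n=4, statistic="attention")
        r2 = cluster_markers(a[perm], labels[perm], list("wxyz"), top_n=4, statistic="attention")
        for k in r1:
            assert r1[k].genes == r2[k].genes


class TestAttentionCorrelation:
    def test_identical_mean_vectors_correlate_perfectly(self):
        a = np.tile([0.5, 0.3, 0.2], (4, 1))
        corr = attention_correlation(a, ["a", "a", "b", "b"])
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_hand_pearson_value(self):
        a = np.array([[0.5, 0.3, 0.2], [0.2, 0.3, 0.5]])
        corr = attention_correlation(a, ["p", "q"])
        assert corr.loc["p", "q"] == pytest.approx(-13 / 14)
        assert corr.loc["q", "p"] == pytest.approx(-13 / 14)

    def test_unit_diagonal_exactly(self, small_attention, small_trained):
        ds, _, _ = small_trained
        corr = attention_correlation(small_attention, ds.labels)
        np.testing.assert_array_equal(np.diag(corr.to_numpy()), 1.0)
        np.testing.assert_allclose(corr.to_numpy(), corr.to_numpy().T)

    def test_zero_variance_class_yields_missing_not_zero(self):
        a = np.array([[0.25, 0.25, 0.25, 0.25], [0.4, 0.3, 0.2, 0.1]])
        corr = attention_correlation(a, ["flat", "varied"])
        assert np.isnan(corr.loc["flat", "varied"])


class TestEnrich:
    BACKGROUND = [f"G{i}" for i in range(20)]

    def test_worked_hypergeometric_case(self):
        # M=20, K=5, n=4, k=4 -> C(5,4)*C(15,0)/C(20,4) = 5/4845
        library = {"term": [f"G{i}" for i in range(5)]}
        res = enrich([f"G{i}" for i in range(4)], library, self.BACKGROUND)
        assert res[0].overlap == 4
        assert res[0].p_value == pytest.approx(5 / 4845, rel=1e-10)

    def test_zero_overlap_p_is_one(self):
        library = {"term": ["G0", "G1"]}
        res = enrich(["G10", "G11"], library, self.BACKGROUND)
        assert res[0].overlap == 0
        assert res[0].p_value == 1.0

    def test_single_term_adjusted_equals_raw(self):
        library = {"only": ["G0", "G1", "G2"]}
        res = enrich(["G0", "G1"], library, self.BACKGROUND)
        assert res[0].adjusted_p == res[0].p_value

    def test_matches_exhaustive_enumeration(self):
        # exact combinatorial upper-tail oracle on small backgrounds
        def exact_upper_tail(m, big_k, n, k):
            total = 0.0
            for i in range(k, min(big_k, n) + 1):
                total += (
                    math.comb(big_k, i) * math.comb(m - big_k, n - i) / math.comb(m, n)
                )
            return total

        for m in (10, 20, 30):
            background = [f"G{i}" for i in range(m)]
            for big_k in (2, 5, m // 2):
                library = {"t": background[:big_k]}
                for n in (1, 3, min(8, m - big_k)):
                    for k in range(0, min(big_k, n) + 1):
                        query = background[:k] + background[big_k : big_k + n - k]
                        res = enrich(query, library, background)
                        assert res[0].overlap == k
                        assert res[0].p_value == pytest.approx(
                            exact_upper_tail(m, big_k, n, k), abs=1e-12
                        )

    def test_bh_adjusted_monotone_in_raw_order(self):
        rng = np.random.default_rng(3)
        background = [f"G{i}" for i in range(30)]
        library = {
            f"t{j}": list(rng.choice(background, size=6, replace=False)) for j in range(8)
        }
        res = enrich(background[:5], library, background)
        in_raw_order = sorted(res, key=lambda r: r.p_value)
        adj = [r.adjusted_p for r in in_raw_order]
        assert all(a <= b + 1e-15 for a, b in zip(adj, adj[1:]))
        assert all(r.adjusted_p >= r.p_value for r in res)

    def test_empty_library_raises(self):
        with pytest.raises(ValueError, match="empty"):
            enrich(["G0"], {}, self.BACKGROUND)

    def test_case_insensitive_matching(self):
        library = {"term": ["g0", "g1"]}
        res = enrich(["G0", "G1"], library, self.BACKGROUND)
        assert res[0].overlap == 2


class TestAnnotateClusters:
    def test_planted_library_annotates_every_cluster(self, small_trained, small_attention):
        ds, _, _ = small_trained
        ann = annotate_clusters(
            small_attention,
            ds.labels,
            ds.matrix.gene_names,
            ds.library,
            top_n=20,
            counts=ds.matrix.counts,
        )
        for cluster, result in ann.items():
            assert result.call == cluster

    def test_disjoint_library_leaves_unassigned(self):
        a = np.full((4, 6), 1 / 6)
        library = {"alien": ["ZZ1", "ZZ2"]}
        ann = annotate_clusters(a, ["x"] * 2 + ["y"] * 2, list("abcdef"), library, top_n=3)
        for result in ann.values():
            assert result.call is None
            assert all(r.adjusted_p == 1.0 for r in result.results)

    def test_identical_terms_tie_is_reported(self):
        rng = np.random.default_rng(4)
        raw = rng.random((4, 6))
        a = raw / raw.sum(axis=1, keepdims=True)
        names = list("abcdef")
        library = {"first": ["a", "b", "c"], "twin": ["a", "b", "c"]}
        ann = annotate_clusters(a, ["x"] * 4, names, library, top_n=3)
        result = ann["x"]
        if result.results[0].adjusted_p < 0.05:
            assert result.call is None
            assert set(result.tied_calls) == {"first", "twin"}
        assert result.results[0].p_value == result.results[1].p_value
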
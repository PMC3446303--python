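"""Complete-linkage clustering, tree cutting and container superimposition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import linkage

from nestnet import (
    Dendrogram,
    HierGraph,
    NestHCParams,
    build_dendrogram,
    cut_clusters,
    nest_dendrogram,
    rootdist,
    threshold_for_k,
)

from oracles import naive_complete_linkage


def balanced4():
    # pairs (a,b) and (c,d) far apart: merges at heights 1, 1, 10
    X = np.array([[0.0], [1.0], [10.0], [11.0]])
    return build_dendrogram(X, labels=list("abcd"))


def caterpillar4():
    # (((a,b),c),d) under complete linkage on the 1-D line
    X = np.array([[0.0], [1.0], [3.0], [9.0]])
    return build_dendrogram(X, labels=list("abcd"))


class TestBuildDendrogram:
    def test_two_rows_merge_at_their_distance(self):
        d = build_dendrogram(np.array([[0.0, 0.0], [3.0, 4.0]]), labels=["a", "b"])
        assert d.merges == [(-1, -2, 5.0)]

    def test_complete_linkage_uses_maximum_distance(self):
        d = build_dendrogram(np.array([[0.0], [1.0], [10.0]]), labels=list("abc"))
        assert d.merges[0] == (-1, -2, 1.0)
        assert d.merges[1][2] == pytest.approx(10.0)  # max(|0-10|, |1-10|)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            build_dendrogram(np.array([[1.0]]), labels=["a"])

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            build_dendrogram(np.array([[0.0], [np.nan]]))

    def test_tie_break_is_lexicographic_on_cluster_minima(self):
        # colinear points: (p,q) and (q,r) tie exactly at distance 1
        X = np.array([[0.0], [1.0], [2.0]])
        d = build_dendrogram(X, labels=["p", "q", "r"])
        assert d.merges[0][:2] == (-1, -2)  # (p,q) wins over (q,r)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 11))
        X = rng.normal(size=(n, 3))
        labels = [f"x{i:02d}" for i in range(n)]
        d = build_dendrogram(X, labels)
        for got, exp in zip(d.merges, naive_complete_linkage(X.tolist(), labels)):
            assert {got[0], got[1]} == {exp[0], exp[1]}
            assert got[2] == pytest.approx(exp[2], abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_heights_match_scipy_complete_linkage(self, seed):
        """Independent library cross-check on the merge-height multiset."""
        rng = np.random.default_rng(100 + seed)
        X = rng.normal(size=(9, 4))
        d = build_dendrogram(X)
        Z = linkage(X, method="complete", metric="euclidean")
        assert np.allclose(
            sorted(h for _, _, h in d.merges), sorted(Z[:, 2]), atol=1e-9
        )

    def test_monotone_heights_under_complete_linkage(self):
        rng = np.random.default_rng(7)
        d = build_dendrogram(rng.normal(size=(12, 2)))
        heights = [h for _, _, h in d.merges]
        assert heights == sorted(heights)


class TestRootdist:
    def test_two_leaf_root_depth_zero(self):
        d = build_dendrogram(np.array([[0.0], [1.0]]), labels=["a", "b"])
        assert rootdist(d) == {1: 0}

    def test_balanced_children_at_depth_one(self):
        depths = rootdist(balanced4())
        assert depths[3] == 0
        assert sorted(depths[s] for s in (1, 2)) == [1, 1]

    def test_caterpillar_spine_depths(self):
        d = caterpillar4()
        depths = rootdist(d)
        assert [depths[s] for s in (3, 2, 1)] == [0, 1, 2]


class TestCutClusters:
    def test_cutlevel_zero_is_one_cluster(self):
        d = balanced4()
        assert cut_clusters(d, NestHCParams("rootdist", 0)) == [set("abcd")]

    def test_balanced_cut_at_depth_one(self):
        d = balanced4()
        assert cut_clusters(d, NestHCParams("rootdist", 1)) == [
            {"a", "b"},
            {"c", "d"},
        ]

    def test_caterpillar_detaches_late_leaf(self):
        d = caterpillar4()
        assert cut_clusters(d, NestHCParams("rootdist", 1)) == [
            {"a", "b", "c"},
            {"d"},
        ]

    def test_cut_below_tree_gives_singletons(self):
        d = balanced4()
        assert cut_clusters(d, NestHCParams("rootdist", 5)) == [
            {"a"}, {"b"}, {"c"}, {"d"},
        ]

    @pytest.mark.parametrize(
        "threshold,expected",
        [
            (100.0, [set("abcd")]),
            (5.0, [{"a", "b"}, {"c", "d"}]),
            (0.5, [{"a"}, {"b"}, {"c"}, {"d"}]),
        ],
    )
    def test_height_cut_regimes(self, threshold, expected):
        d = balanced4()
        assert cut_clusters(d, NestHCParams("height", threshold)) == expected

    @given(st.integers(0, 2**31 - 1), st.integers(0, 6))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_cut_is_always_a_partition(self, seed, cutlevel):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 12))
        d = build_dendrogram(rng.normal(size=(n, 2)))
        clusters = cut_clusters(d, NestHCParams("rootdist", cutlevel))
        union = set().union(*clusters)
        assert union == set(d.leaf_labels)
        assert sum(len(c) for c in clusters) == n  # disjoint

    def test_threshold_for_k_yields_k_clusters(self):
        rng = np.random.default_rng(3)
        d = build_dendrogram(rng.normal(size=(10, 3)))
        for k in (1, 2, 5, 10):
            t = threshold_for_k(d, k)
            assert len(cut_clusters(d, NestHCParams("height", t))) == k


class TestNestDendrogram:
    def _graph_for(self, d):
        g = HierGraph()
        for lab in d.leaf_labels:
            g.add_node(lab)
        return g

    def test_outermost_partition_matches_cut(self):
        d = balanced4()
        g = self._graph_for(d)
        params = NestHCParams("rootdist", 1)
        created = nest_dendrogram(g, d, params)
        got = sorted(
            (g.leaf_descendants(c) for c in created), key=lambda s: min(s)
        )
        expected = [c for c in cut_clusters(d, params) if len(c) >= 2]
        assert got == expected

    def test_two_level_nesting(self):
        # balanced 8-leaf tree: 2 outer containers each holding 2 inner ones
        X = np.array([[v] for v in (0, 1, 10, 11, 100, 101, 110, 111)], float)
        d = build_dendrogram(X, labels=list("abcdefgh"))
        g = self._graph_for(d)
        created = nest_dendrogram(g, d, NestHCParams("rootdist", 1, nlev=2))
        outer = [c for c in created if g.node(c).parent is None]
        assert len(outer) == 2
        for c in outer:
            inner = [x for x in g.children(c) if g.node(x).kind == "container"]
            assert len(inner) == 2
        assert g.depth("a") == 2

    def test_singletons_create_no_container(self):
        d = caterpillar4()
        g = self._graph_for(d)
        created = nest_dendrogram(g, d, NestHCParams("rootdist", 1))
        assert len(created) == 1
        assert g.node("d").parent is None

    def test_cut_past_tree_leaves_graph_unchanged(self):
        d = balanced4()
        g = self._graph_for(d)
        created = nest_dendrogram(g, d, NestHCParams("rootdist", 9))
        assert created == []
        assert g.container_ids() == []

    def test_label_mismatch_rejected(self):
        d = balanced4()
        g = HierGraph()
        g.add_node("a")
        with pytest.raises(Exception, match="labels"):
            nest_dendrogram(g, d, NestHCParams("rootdist", 1))

    def test_replaces_prior_containment(self):
        d = balanced4()
        g = self._graph_for(d)
        g.nest({"a", "c"}, "OLD")
        created = nest_dendrogram(g, d, NestHCParams("rootdist", 1))
        assert "OLD" not in g  # emptied by re-parenting, pruned
        assert {g.node("a").parent, g.node("c").parent} == set(created)


class TestDendrogramValidation:
    def test_merge_count_must_match_leaves(self):
        with pytest.raises(ValueError):
            Dendrogram(leaf_labels=["a", "b", "c"], merges=[(-1, -2, 1.0)])

    def test_double_reference_rejected(self):
        with pytest.raises(ValueError, match="twice"):
            Dendrogram(
                leaf_labels=["a", "b", "c"],
                merges=[(-1, -2, 1.0), (-1, 1, 2.0)],
            )
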
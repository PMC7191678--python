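import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spotpie import (
    ExpressionMatrix,
    MultiResolutionClustering,
    ResolutionSpec,
    assign_colors,
    build_cluster_graph,
    filter_edges,
    top_genes,
)
def mrc_from_labels(labels_per_res: dict[str, list[int]]) -> MultiResolutionClustering:
    n = len(next(iter(labels_per_res.values())))
    return MultiResolutionClustering(
        spot_ids=tuple(f"{i + 1}x1" for i in range(n)),
        resolutions=tuple(
            ResolutionSpec(label, max(v)) for label, v in labels_per_res.items()
        ),
        assignments={k: np.array(v) for k, v in labels_per_res.items()},
    )


def matrix_for(n_spots: int, n_genes: int = 4, seed: int = 0) -> ExpressionMatrix:
    rng = np.random.default_rng(seed)
    return ExpressionMatrix(
        rng.random((n_spots, n_genes)) + 0.01,
        tuple(f"{i + 1}x1" for i in range(n_spots)),
        tuple(f"g{j}" for j in range(n_genes)),
        normalized=True,
    )


def brute_force_proportions(parent, child):
    """Per-pair overlap counts over child sizes, spot by spot."""
    out = {}
    for p in set(parent):
        for c in set(child):
            inter = sum(1 for a, b in zip(parent, child) if a == p and b == c)
            if inter:
                out[(p, c)] = inter / sum(1 for b in child if b == c)
    return out


class TestOverlapEdges:
    def test_counting_example(self):
        # child cluster 1 = {a,b,c,d}; parents: a,b,c -> 1, d -> 2
        mrc = mrc_from_labels({"lo": [1, 1, 1, 2], "hi": [1, 1, 1, 1]})
        graph = build_cluster_graph(matrix_for(4), mrc)
        props = {(e.parent[1], e.child[1]): e.proportion for e in graph.edges}
        assert props == {(1, 1): 0.75, (2, 1): 0.25}

    def test_full_containment_single_edge(self):
        mrc = mrc_from_labels({"lo": [1, 1, 2, 2], "hi": [1, 1, 2, 3]})
        graph = build_cluster_graph(matrix_for(4), mrc)
        incoming = [e for e in graph.edges if e.child == ("hi", 1)]
        assert len(incoming) == 1 and incoming[0].proportion == 1.0

    def test_identical_assignments_bijective_unit_edges(self):
        mrc = mrc_from_labels({"lo": [1, 2, 1, 2], "hi": [1, 2, 1, 2]})
        graph = build_cluster_graph(matrix_for(4), mrc)
        assert len(graph.edges) == 2
        assert all(e.proportion == 1.0 for e in graph.edges)
        assert all(e.parent[1] == e.child[1] for e in graph.edges)

    def test_mismatched_spots_rejected(self):
        mrc = mrc_from_labels({"lo": [1, 1, 2], "hi": [1, 2, 2]})
        with pytest.raises(ValueError, match="spot sets"):
            build_cluster_graph(matrix_for(4), mrc)

    @settings(deadline=None, max_examples=40)
    @given(st.data())
    def test_conservation_and_brute_force_equivalence(self, data):
        """Incoming proportions of each child sum to 1 and match brute force."""
        n = data.draw(st.integers(4, 30))
        n_res = data.draw(st.integers(2, 4))
        labels = {}
        for r in range(n_res):
            k = data.draw(st.integers(1, min(5, n)))
            raw = data.draw(st.lists(st.integers(1, k), min_size=n, max_size=n))
            remap: dict[int, int] = {}
            vec = [remap.setdefault(v, len(remap) + 1) for v in raw]
            # renumber to the canonical consecutive-from-1 convention
            order = sorted(set(vec))
            vec = [order.index(v) + 1 for v in vec]
            labels[f"r{r}"] = vec
        mrc = mrc_from_labels(labels)
        graph = build_cluster_graph(matrix_for(n), mrc)
        order = list(labels)
        for lo, hi in zip(order, order[1:]):
            edges = [e for e in graph.edges if e.parent[0] == lo and e.child[0] == hi]
            expected = brute_force_proportions(labels[lo], labels[hi])
            got = {(e.parent[1], e.child[1]): e.proportion for e in edges}
            assert got == pytest.approx(expected)
            for c in set(labels[hi]):
                total = sum(p for (pp, cc), p in got.items() if cc == c)
                assert total == pytest.approx(1.0, abs=1e-12)

    def test_weighted_size_conservation(self):
        mrc = mrc_from_labels({"lo": [1, 1, 1, 2, 2], "hi": [1, 2, 2, 2, 3]})
        graph = build_cluster_graph(matrix_for(5), mrc)
        child_sizes = {n.cluster_label: n.size for n in graph.nodes_at("hi")}
        for parent_node in graph.nodes_at("lo"):
            mass = sum(
                child_sizes[e.child[1]] * e.proportion
                for e in graph.edges
                if e.parent == parent_node.key
            )
            assert mass == pytest.approx(parent_node.size)


class TestFilterEdges:
    def _graph(self):
        mrc = mrc_from_labels({"lo": [1, 1, 1, 2], "hi": [1, 1, 1, 1]})
        return build_cluster_graph(matrix_for(4), mrc)

    def test_threshold_removes_small_edges(self):
        filtered = filter_edges(self._graph(), 0.3)
        assert [e.proportion for e in filtered.edges] == [0.75]
        assert filtered.threshold_applied == 0.3

    def test_zero_threshold_noop(self):
        graph = self._graph()
        assert filter_edges(graph, 0.0).edges == graph.edges

    def test_orphaned_child_allowed(self):
        filtered = filter_edges(self._graph(), 0.8)
        assert filtered.edges == ()
        assert len(filtered.nodes) == len(self._graph().nodes)

    def test_threshold_one_rejected(self):
        with pytest.raises(ValueError, match="\\[0, 1\\)"):
            filter_edges(self._graph(), 1.0)


class TestAssignColors:
    def test_identical_centroids_identical_colors(self):
        cents = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [5.0, 0.0, 1.0]])
        colors = assign_colors(cents)
        np.testing.assert_allclose(colors[0], colors[1])
        assert not np.allclose(colors[0], colors[2])

    def test_single_centroid_gray(self):
        np.testing.assert_allclose(assign_colors(np.array([[3.0, 1.0]])), [[0.5, 0.5, 0.5]])

    def test_collinear_midpoint_color_is_midpoint(self):
        a = np.array([0.0, 0.0, 0.0, 0.0])
        b = np.array([4.0, 2.0, 0.0, 6.0])
        colors = assign_colors(np.vstack([a, (a + b) / 2, b]))
        np.testing.assert_allclose(colors[1], (colors[0] + colors[2]) / 2, atol=1e-12)

    def test_matches_independent_pca(self):
        """Colors reproduce an sklearn-PCA + min-max computation up to sign."""
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(5)
        cents = rng.random((8, 12))
        colors = assign_colors(cents)
        scores = PCA(n_components=3).fit_transform(cents)
        expected = np.empty_like(scores)
        totals = cents.sum(axis=1)
        for j in range(3):
            s = scores[:, j]
            if np.dot(s - s.mean(), totals - totals.mean()) < 0:
                s = -s
            expected[:, j] = (s - s.min()) / (s.max() - s.min())
        np.testing.assert_allclose(colors, expected, atol=1e-9)

    def test_components_in_unit_interval(self):
        rng = np.random.default_rng(0)
        colors = assign_colors(rng.random((10, 6)))
        assert colors.min() >= 0 and colors.max() <= 1

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        cents = rng.random((6, 9))
        perm = rng.permutation(6)
        np.testing.assert_allclose(
            assign_colors(cents)[perm], assign_colors(cents[perm]), atol=1e-9
        )

    def test_rank_deficient_fills_half(self):
        # two distinct centroids: rank 1 -> components 2,3 fill with 0.5
        colors = assign_colors(np.array([[0.0, 0.0], [1.0, 1.0]]))
        np.testing.assert_allclose(colors[:, 1:], 0.5)
        assert colors[0, 0] != colors[1, 0]


class TestTopGenes:
    def test_sorting(self):
        out = top_genes(np.array([5.0, 1.0, 3.0]), ["g1", "g2", "g3"], 2)
        assert out == (("g1", 5.0), ("g3", 3.0))

    def test_tie_broken_lexicographically(self):
        out = top_genes(np.array([2.0, 2.0, 2.0]), ["gb", "ga", "gc"], 2)
        assert out == (("ga", 2.0), ("gb", 2.0))

    def test_n_zero_rejected_and_truncation(self):
        with pytest.raises(ValueError):
            top_genes(np.array([1.0]), ["g"], 0)
        assert len(top_genes(np.array([1.0, 2.0]), ["a", "b"], 10)) == 2


class TestExports:
    def test_dot_json_tsv_contain_all_edges(self):
        mrc = mrc_from_labels({"lo": [1, 1, 2, 2], "hi": [1, 2, 3, 3]})
        graph = build_cluster_graph(matrix_for(4), mrc)
        dot, tsv = graph.to_dot(), graph.edges_to_tsv()
        assert dot.count("->") == len(graph.edges)
        assert len(tsv.strip().splitlines()) == len(graph.edges) + 1
        import json

        payload = json.loads(graph.to_json())
        assert len(payload["nodes"]) == len(graph.nodes)
        assert len(payload["edges"]) == len(graph.edges)

    def test_networkx_view(self):
        mrc = mrc_from_labels({"lo": [1, 1, 2, 2], "hi": [1, 2, 3, 3]})
        g = build_cluster_graph(matrix_for(4), mrc).to_networkx()
        assert g.number_of_nodes() == 5
        assert all(0 < d["proportion"] <= 1 for _, _, d in g.edges(data=True))
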
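import math

import numpy as np
import pytest

from spotpie import (
    ExpressionMatrix,
    MultiResolutionClustering,
    RenderSpec,
    ResolutionSpec,
    SimilarityResult,
    SpotCoordinates,
    build_cluster_graph,
    export_report,
    render_array_plot,
    render_cluster_graph,
)
from spotpie.render import pie_angles


@pytest.fixture
def small_graph():
    rng = np.random.default_rng(0)
    matrix = ExpressionMatrix(
        rng.random((4, 3)) + 0.01,
        ("1x1", "1x2", "2x1", "2x2"),
        ("g1", "g2", "g3"),
        normalized=True,
    )
    mrc = MultiResolutionClustering(
        spot_ids=matrix.spot_ids,
        resolutions=(ResolutionSpec("lo", 1), ResolutionSpec("hi", 2)),
        assignments={"lo": np.array([1, 1, 1, 1]), "hi": np.array([1, 1, 2, 2])},
    )
    return matrix, mrc, build_cluster_graph(matrix, mrc)


def make_result(proportions: np.ndarray, label="hi") -> SimilarityResult:
    proportions = np.asarray(proportions, dtype=float)
    scores = proportions / proportions.max(axis=1, keepdims=True)
    return SimilarityResult(
        resolution_label=label,
        spot_ids=tuple(f"1x{i + 1}" for i in range(proportions.shape[0])),
        scores=scores,
        proportions=proportions,
        lambda_used=1.0,
    )


class TestPieAngles:
    def test_angles_sum_to_full_turn(self):
        angles = pie_angles([0.2, 0.3, 0.5])
        assert angles[0][0] == 0.0
        assert angles[-1][1] == pytest.approx(2 * math.pi, abs=1e-9)
        sweeps = [a1 - a0 for a0, a1 in angles]
        assert sum(sweeps) == pytest.approx(2 * math.pi, abs=1e-9)

    def test_uniform_slices_equal(self):
        sweeps = [a1 - a0 for a0, a1 in pie_angles([0.25] * 4)]
        assert all(s == pytest.approx(math.pi / 2) for s in sweeps)

    def test_half_half_semicircles(self):
        angles = pie_angles([0.5, 0.5])
        assert angles == [(0.0, pytest.approx(math.pi)), (pytest.approx(math.pi), pytest.approx(2 * math.pi))]


class TestRenderClusterGraph:
    def test_structure_counts(self, small_graph, tmp_path):
        _, _, graph = small_graph
        out = tmp_path / "g.svg"
        render_cluster_graph(graph, RenderSpec(), out)
        svg = out.read_text()
        assert svg.count('class="node"') == 3
        assert svg.count('class="edge"') == 2

    def test_byte_identical_rerun(self, small_graph, tmp_path):
        _, _, graph = small_graph
        a, b = tmp_path / "a.svg", tmp_path / "b.svg"
        render_cluster_graph(graph, RenderSpec(), a)
        render_cluster_graph(graph, RenderSpec(), b)
        assert a.read_bytes() == b.read_bytes()

    def test_unit_proportion_maps_to_alpha_max(self, small_graph, tmp_path):
        _, _, graph = small_graph
        spec = RenderSpec(edge_alpha_range=(0.2, 0.9))
        out = tmp_path / "g.svg"
        render_cluster_graph(graph, spec, out)
        # both children are fully contained in the single parent
        assert 'stroke-opacity="0.9"' in out.read_text()
        assert spec.edge_alpha(1.0) == pytest.approx(0.9)

    def test_tooltip_contains_top_genes(self, small_graph, tmp_path):
        _, _, graph = small_graph
        out = tmp_path / "g.svg"
        render_cluster_graph(graph, RenderSpec(), out)
        assert "<title>" in out.read_text()

    def test_png_output(self, small_graph, tmp_path):
        _, _, graph = small_graph
        out = tmp_path / "g.png"
        render_cluster_graph(graph, RenderSpec(), out)
        assert out.read_bytes()[:8] == b"\x89PNG\r\n\x1a\n"


class TestRenderArrayPlot:
    COLORS = {1: (1.0, 0.0, 0.0), 2: (0.0, 0.0, 1.0)}

    def test_full_disc_for_unit_proportion(self, tmp_path):
        result = make_result([[1.0]])
        coords = SpotCoordinates({"1x1": (1, 1)})
        out = tmp_path / "a.svg"
        render_array_plot(result, coords, {1: (0.3, 0.3, 0.3)}, RenderSpec(), out)
        svg = out.read_text()
        assert svg.count('class="slice"') == 1
        assert "<circle" in svg  # degenerate pie drawn as a disc

    def test_two_semicircles(self, tmp_path):
        result = make_result([[0.5, 0.5]])
        coords = SpotCoordinates({"1x1": (1, 1)})
        out = tmp_path / "a.svg"
        render_array_plot(result, coords, self.COLORS, RenderSpec(), out)
        assert out.read_text().count("<path") == 2

    def test_missing_coordinate_named(self, tmp_path):
        result = make_result([[0.5, 0.5], [0.4, 0.6]])
        coords = SpotCoordinates({"1x1": (1, 1)})
        with pytest.raises(KeyError, match="1x2"):
            render_array_plot(result, coords, self.COLORS, RenderSpec(), tmp_path / "a.svg")

    def test_deterministic(self, tmp_path):
        result = make_result([[0.2, 0.8], [0.6, 0.4]])
        coords = SpotCoordinates({"1x1": (1, 1), "1x2": (1, 2)})
        a, b = tmp_path / "a.svg", tmp_path / "b.svg"
        for p in (a, b):
            render_array_plot(result, coords, self.COLORS, RenderSpec(), p)
        assert a.read_bytes() == b.read_bytes()


class TestExportReport:
    def test_manifest_and_color_consistency(self, small_graph, tmp_path):
        matrix, mrc, graph = small_graph
        from spotpie import ScoreConfig, compute_centroids, similarity_scores

        coords = SpotCoordinates(
            {s: (float(s[0]), float(s[2])) for s in matrix.spot_ids}
        )
        results = [
            similarity_scores(
                matrix,
                compute_centroids(matrix, mrc.assignments[label]),
                ScoreConfig(mode="fixed", lambda_=1.0),
                label,
            )
            for label in mrc.resolution_labels
        ]
        manifest = export_report(graph, results, coords, mrc, tmp_path / "out", {"seed": 0})
        names = set(manifest["files"])
        assert {"cluster_graph.svg", "cluster_graph.dot", "cluster_graph.json",
                "array_lo.svg", "array_hi.svg", "scores_lo.tsv", "scores_hi.tsv",
                "assignments.tsv"} <= names
        # slice fill colors in the array plot equal node colors in the graph
        array_svg = (tmp_path / "out" / "array_hi.svg").read_text()
        for node in graph.nodes_at("hi"):
            assert node.hex_color in array_svg
            assert node.hex_color in (tmp_path / "out" / "cluster_graph.svg").read_text()

    def test_rerun_identical_checksums(self, small_graph, tmp_path):
        matrix, mrc, graph = small_graph
        from spotpie import ScoreConfig, compute_centroids, similarity_scores

        coords = SpotCoordinates({s: (float(s[0]), float(s[2])) for s in matrix.spot_ids})
        results = [
            similarity_scores(
                matrix, compute_centroids(matrix, mrc.assignments[label]),
                ScoreConfig(mode="fixed", lambda_=1.0), label,
            )
            for label in mrc.resolution_labels
        ]
        m1 = export_report(graph, results, coords, mrc, tmp_path / "o1", {"seed": 0})
        m2 = export_report(graph, results, coords, mrc, tmp_path / "o2", {"seed": 0})
        assert m1["files"] == m2["files"]
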
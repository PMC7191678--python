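"""Cross-resolution cluster graph: overlap edges, colors, top genes.

The cluster graph relates partitions obtained at different resolutions.
Each non-empty cluster at each resolution is a node; for every pair of
consecutive resolutions (in the order the user listed them) an edge runs
from a parent cluster P at the lower-listed resolution to a child cluster C
at the next one whenever they share spots, weighted by the fraction of the
child's spots found in the parent:

    proportion(P -> C) = |C ∩ P| / |C|

so the incoming proportions of every child sum to one.  Nodes carry the
cluster centroid, its size, a color from a shared PCA embedding of all
centroids, and a top-gene summary, which makes node identity legible across
both the graph and the spatial array plots.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .cluster import MultiResolutionClustering, compute_centroids
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_EDGE_THRESHOLD = 0.05
DEFAULT_TOP_N_GENES = 5


@dataclass(frozen=True)
class ClusterNode:
    resolution_label: str
    cluster_label: int
    size: int
    centroid: np.ndarray
    color: tuple[float, float, float]
    top_genes: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("cluster node must contain at least one spot")
        if not all(0.0 <= c <= 1.0 for c in self.color):
            raise ValueError(f"color components outside [0,1]: {self.color}")

    @property
    def key(self) -> tuple[str, int]:
        return (self.resolution_label, self.cluster_label)

    @property
    def hex_color(self) -> str:
        r, g, b = (int(round(c * 255)) for c in self.color)
        return f"#{r:02x}{g:02x}{b:02x}"


@dataclass(frozen=True)
class ClusterEdge:
    parent: tuple[str, int]  # (resolution_label, cluster_label), lower resolution
    child: tuple[str, int]  # next-listed (higher) resolution
    proportion: float

    def __post_init__(self) -> None:
        if not 0.0 < self.proportion <= 1.0 + 1e-12:
            raise ValueError(f"edge proportion {self.proportion} outside (0, 1]")


@dataclass(frozen=True)
class ClusterGraph:
    nodes: tuple[ClusterNode, ...]
    edges: tuple[ClusterEdge, ...]
    resolution_order: tuple[str, ...]
    threshold_applied: float = 0.0

    def node(self, resolution_label: str, cluster_label: int) -> ClusterNode:
        for n in self.nodes:
            if n.key == (resolution_label, cluster_label):
                return n
        raise KeyError((resolution_label, cluster_label))

    def nodes_at(self, resolution_label: str) -> list[ClusterNode]:
        out = [n for n in self.nodes if n.resolution_label == resolution_label]
        return sorted(out, key=lambda n: n.cluster_label)

    def colors_at(self, resolution_label: str) -> dict[int, tuple[float, float, float]]:
        return {n.cluster_label: n.color for n in self.nodes_at(resolution_label)}

    def to_networkx(self):
        """Directed graph view for downstream analysis (networkx)."""
        import networkx as nx

        g = nx.DiGraph()
        for n in self.nodes:
            g.add_node(
                n.key,
                resolution=n.resolution_label,
                cluster=n.cluster_label,
                size=n.size,
                color=n.hex_color,
                top_genes=list(n.top_genes),
            )
        for e in self.edges:
            g.add_edge(e.parent, e.child, proportion=e.proportion)
        return g

    def to_json(self) -> str:
        payload = {
            "resolution_order": list(self.resolution_order),
            "threshold_applied": self.threshold_applied,
            "nodes": [
                {
                    "resolution": n.resolution_label,
                    "cluster": n.cluster_label,
                    "size": n.size,
                    "color": n.hex_color,
                    "top_genes": [[g, round(v, 6)] for g, v in n.top_genes],
                }
                for n in self.nodes
            ],
            "edges": [
                {
                    "parent_resolution": e.parent[0],
                    "parent": e.parent[1],
                    "child_resolution": e.child[0],
                    "child": e.child[1],
                    "proportion": round(e.proportion, 10),
                }
                for e in self.edges
            ],
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def to_dot(self) -> str:
        """Layered DOT export: one rank per resolution, styled nodes/edges."""
        lines = ["digraph cluster_graph {", "  rankdir=TB;", "  node [style=filled];"]
        for label in self.resolution_order:
            names = " ".join(
                f'"{n.resolution_label}:{n.cluster_label}"' for n in self.nodes_at(label)
            )
            lines.append(f"  {{ rank=same; {names} }}")
        for n in self.nodes:
            tooltip = ", ".join(f"{g} ({v:.3g})" for g, v in n.top_genes)
            lines.append(
                f'  "{n.resolution_label}:{n.cluster_label}" '
                f'[fillcolor="{n.hex_color}" label="{n.cluster_label}" '
                f'tooltip="{tooltip}"];'
            )
        for e in self.edges:
            lines.append(
                f'  "{e.parent[0]}:{e.parent[1]}" -> "{e.child[0]}:{e.child[1]}" '
                f"[penwidth={1 + 4 * e.proportion:.3f} "
                f'alpha="{e.proportion:.4f}"];'
            )
        lines.append("}")
        return "\n".join(lines) + "\n"

    def edges_to_tsv(self) -> str:
        rows = ["parent_resolution\tparent\tchild_resolution\tchild\tproportion"]
        for e in self.edges:
            rows.append(
                f"{e.parent[0]}\t{e.parent[1]}\t{e.child[0]}\t{e.child[1]}\t"
                f"{e.proportion:.10g}"
            )
        return "\n".join(rows) + "\n"


def assign_colors(centroids: np.ndarray) -> np.ndarray:
    """Embed centroid expression profiles into RGB via PCA.

    The pooled centroid rows (across *all* resolutions) are mean-centered —
    not variance-scaled — and projected onto their first up-to-three
    principal axes; each used component is min-max scaled to [0,1] and read
    as (r, g, b), missing components filling with 0.5.  Pooling yields one
    shared embedding, so similar clusters get similar colors everywhere:
    in the graph and in every array plot.

    Each axis is oriented so that its scores correlate nonnegatively with
    the centroid totals, removing PCA's sign ambiguity.
    """
    centroids = np.asarray(centroids, dtype=float)
    if centroids.ndim != 2 or centroids.shape[0] < 1:
        raise ValueError("need a 2-D matrix with at least one centroid row")
    n = centroids.shape[0]
    colors = np.full((n, 3), 0.5)
    if n == 1:
        return colors
    centered = centroids - centroids.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    tol = s.max(initial=0.0) * max(centered.shape) * np.finfo(float).eps
    rank = int((s > tol).sum())
    n_comp = min(3, rank)
    totals = centroids.sum(axis=1)
    for j in range(n_comp):
        scores = centered @ vt[j]
        # orient: nonnegative covariance with centroid totals; fall back to
        # making the largest-|loading| coefficient positive
        cov = float(np.dot(scores - scores.mean(), totals - totals.mean()))
        if cov < 0:
            scores = -scores
        elif cov == 0 and vt[j][np.argmax(np.abs(vt[j]))] < 0:
            scores = -scores
        lo, hi = scores.min(), scores.max()
        if hi - lo <= tol:
            colors[:, j] = 0.5
        else:
            colors[:, j] = (scores - lo) / (hi - lo)
    return colors


def top_genes(
    centroid: np.ndarray, gene_names: Sequence[str], n: int = DEFAULT_TOP_N_GENES
) -> tuple[tuple[str, float], ...]:
    """The n most-expressed genes of a centroid, descending; ties by name."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    centroid = np.asarray(centroid, dtype=float)
    if centroid.shape != (len(gene_names),):
        raise ValueError("centroid length does not match gene_names")
    if n > len(gene_names):
        logger.info("top_genes: n=%d truncated to %d genes", n, len(gene_names))
        n = len(gene_names)
    pairs = sorted(
        zip(gene_names, centroid), key=lambda gv: (-gv[1], gv[0])
    )
    return tuple((g, float(v)) for g, v in pairs[:n])


def overlap_proportions(parent: np.ndarray, child: np.ndarray) -> dict[tuple[int, int], float]:
    """Edge weights between two label vectors over the same spots.

    Returns ``{(p, c): |C_c ∩ P_p| / |C_c|}`` for all co-occurring pairs.
    """
    parent = np.asarray(parent, dtype=int)
    child = np.asarray(child, dtype=int)
    if parent.shape != child.shape:
        raise ValueError("label vectors differ in length")
    out: dict[tuple[int, int], float] = {}
    child_sizes = np.bincount(child)
    pairs, counts = np.unique(np.stack([parent, child]), axis=1, return_counts=True)
    for (p, c), cnt in zip(pairs.T, counts):
        out[(int(p), int(c))] = cnt / child_sizes[c]
    return out


def build_cluster_graph(
    matrix: ExpressionMatrix,
    mrc: MultiResolutionClustering,
    *,
    top_n: int = DEFAULT_TOP_N_GENES,
) -> ClusterGraph:
    """Assemble nodes, overlap edges, colors and summaries for all resolutions."""
    if tuple(matrix.spot_ids) != tuple(mrc.spot_ids):
        raise ValueError("matrix and clustering refer to different spot sets")
    order = mrc.resolution_labels
    if len(order) < 2:
        raise ValueError("cluster graph needs at least two resolutions")
    ks = [mrc.k_effective(label) for label in order]
    if any(b < a for a, b in zip(ks, ks[1:])):
        logger.warning("resolution order is not monotone in cluster count: %s", ks)

    centroids_per_res = {
        label: compute_centroids(matrix, mrc.assignments[label]) for label in order
    }
    pooled = np.vstack([centroids_per_res[label] for label in order])
    colors = assign_colors(pooled)

    nodes: list[ClusterNode] = []
    offset = 0
    for label in order:
        cents = centroids_per_res[label]
        sizes = np.bincount(mrc.assignments[label])
        for c in range(1, cents.shape[0] + 1):
            nodes.append(
                ClusterNode(
                    resolution_label=label,
                    cluster_label=c,
                    size=int(sizes[c]),
                    centroid=cents[c - 1],
                    color=tuple(colors[offset + c - 1]),
                    top_genes=top_genes(cents[c - 1], matrix.gene_names, top_n),
                )
            )
        offset += cents.shape[0]

    edges: list[ClusterEdge] = []
    for lower, higher in zip(order, order[1:]):
        props = overlap_proportions(mrc.assignments[lower], mrc.assignments[higher])
        for (p, c) in sorted(props):
            edges.append(
                ClusterEdge(parent=(lower, p), child=(higher, c), proportion=props[(p, c)])
            )
    return ClusterGraph(
        nodes=tuple(nodes), edges=tuple(edges), resolution_order=tuple(order)
    )


def filter_edges(graph: ClusterGraph, threshold: float) -> ClusterGraph:
    """Drop edges below the overlap threshold; nodes are untouched.

    A child losing all its parents is allowed (and logged): thresholding is a
    display decision and conservation checks run on the unfiltered graph.
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    kept = tuple(e for e in graph.edges if e.proportion >= threshold)
    children_before = {e.child for e in graph.edges}
    children_after = {e.child for e in kept}
    orphaned = children_before - children_after
    if orphaned:
        logger.info("threshold %.3g orphans %d child nodes", threshold, len(orphaned))
    return replace(graph, edges=kept, threshold_applied=threshold)
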
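"""Deterministic SVG rendering of the cluster graph and pie-glyph array plot.

Both renderers emit plain SVG text with no timestamps or random identifiers,
so identical inputs produce byte-identical files — reruns can be compared by
checksum.  Colors come from the shared PCA embedding carried on the cluster
graph, so a cluster's node in the graph and its pie slices in the array plot
always match.  Top-gene summaries are embedded as SVG ``<title>`` elements
(browser hover tooltips), keeping the interactive "hover a node" experience
available in static output.  A ``.png`` extension switches to a matplotlib
raster of the same geometry.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .cluster import MultiResolutionClustering
from .graph import ClusterGraph
from .io import SpotCoordinates
from .scores import SimilarityResult

logger = logging.getLogger(__name__)

_CELL = 30.0  # px per array unit
_MARGIN = 40.0


@dataclass(frozen=True)
class RenderSpec:
    """Rendering knobs: glyph size (array units), DPI, edge-opacity map."""

    glyph_radius: float = 0.45
    figure_dpi: int = 150
    edge_alpha_range: tuple[float, float] = (0.1, 1.0)
    label_nodes: bool = True

    def __post_init__(self) -> None:
        if self.glyph_radius <= 0:
            raise ValueError("glyph_radius must be positive")
        lo, hi = self.edge_alpha_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError(f"invalid edge_alpha_range {self.edge_alpha_range}")

    def edge_alpha(self, proportion: float) -> float:
        lo, hi = self.edge_alpha_range
        return lo + proportion * (hi - lo)


def _fmt(v: float) -> str:
    return f"{v:.4f}".rstrip("0").rstrip(".")


def pie_angles(proportions: Sequence[float]) -> list[tuple[float, float]]:
    """(start, end) angles in radians per slice, 12 o'clock, clockwise.

    Slices follow the input order (cluster label order); angles are measured
    clockwise from the top, and the ends always sum to a full turn.
    """
    total = float(sum(proportions))
    if total <= 0:
        raise ValueError("proportions must have a positive sum")
    angles = []
    start = 0.0
    for p in proportions:
        sweep = 2 * math.pi * (p / total)
        angles.append((start, start + sweep))
        start += sweep
    return angles


def _wedge_path(cx: float, cy: float, r: float, a0: float, a1: float) -> str:
    """SVG path for a clockwise wedge; angle 0 is 12 o'clock."""

    def point(a: float) -> tuple[float, float]:
        return cx + r * math.sin(a), cy - r * math.cos(a)

    x0, y0 = point(a0)
    x1, y1 = point(a1)
    large = 1 if (a1 - a0) > math.pi else 0
    return (
        f"M {_fmt(cx)},{_fmt(cy)} L {_fmt(x0)},{_fmt(y0)} "
        f"A {_fmt(r)},{_fmt(r)} 0 {large} 1 {_fmt(x1)},{_fmt(y1)} Z"
    )


def _svg_document(width: float, height: float, body: list[str]) -> str:
    head = (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{_fmt(width)}" '
        f'height="{_fmt(height)}" viewBox="0 0 {_fmt(width)} {_fmt(height)}">'
    )
    return "\n".join([head, *body, "</svg>"]) + "\n"


def render_cluster_graph(
    graph: ClusterGraph, spec: RenderSpec = RenderSpec(), out: str | Path = "graph.svg"
) -> None:
    """Render the layered cluster graph.

    One horizontal layer per resolution, in the order the resolutions were
    specified; nodes ordered by cluster label within a layer; edge opacity is
    the linear image of the overlap proportion under ``edge_alpha_range``.
    """
    if not graph.nodes:
        raise ValueError("cannot render an empty cluster graph")
    out = Path(out)
    layer_count = len(graph.resolution_order)
    max_width = max(len(graph.nodes_at(label)) for label in graph.resolution_order)
    width = 2 * _MARGIN + max(1, max_width) * 90.0
    height = 2 * _MARGIN + max(1, layer_count - 1) * 110.0
    pos: dict[tuple[str, int], tuple[float, float]] = {}
    for i, label in enumerate(graph.resolution_order):
        nodes = graph.nodes_at(label)
        y = _MARGIN + i * 110.0
        for j, n in enumerate(nodes):
            x = width / 2 + (j - (len(nodes) - 1) / 2) * 90.0
            pos[n.key] = (x, y)

    body = []
    for e in graph.edges:
        (x0, y0), (x1, y1) = pos[e.parent], pos[e.child]
        body.append(
            f'<line class="edge" x1="{_fmt(x0)}" y1="{_fmt(y0)}" '
            f'x2="{_fmt(x1)}" y2="{_fmt(y1)}" stroke="#333333" stroke-width="2" '
            f'stroke-opacity="{_fmt(spec.edge_alpha(e.proportion))}"/>'
        )
    for n in graph.nodes:
        x, y = pos[n.key]
        tooltip = ", ".join(f"{g} ({v:.3g})" for g, v in n.top_genes)
        label_el = (
            f'<text x="{_fmt(x)}" y="{_fmt(y + 4)}" text-anchor="middle" '
            f'font-size="12" font-family="sans-serif">{n.cluster_label}</text>'
            if spec.label_nodes
            else ""
        )
        body.append(
            f'<g class="node"><circle cx="{_fmt(x)}" cy="{_fmt(y)}" '
            f'r="{_fmt(10 + 8 * math.sqrt(n.size / max(m.size for m in graph.nodes)))}" '
            f'fill="{n.hex_color}" stroke="#222222">'
            f"<title>{tooltip}</title></circle>{label_el}</g>"
        )
    for i, label in enumerate(graph.resolution_order):
        body.append(
            f'<text class="layer-label" x="{_fmt(6.0)}" y="{_fmt(_MARGIN + i * 110.0 + 4)}" '
            f'font-size="11" font-family="sans-serif">{label}</text>'
        )
    _write_figure(out, width, height, body, spec)


def render_array_plot(
    result: SimilarityResult,
    coords: SpotCoordinates,
    cluster_colors: Mapping[int, tuple[float, float, float]],
    spec: RenderSpec = RenderSpec(),
    out: str | Path = "array.svg",
) -> None:
    """Render one pie glyph per spot at its array position.

    Slice proportions are the spot's normalized similarity scores; slices
    are ordered by cluster label, starting at 12 o'clock and proceeding
    clockwise, filled with the shared cluster colors.  The y axis is flipped
    so row 1 sits at the top (microscopy convention).
    """
    missing = [s for s in result.spot_ids if s not in coords]
    if missing:
        raise KeyError(f"spots without coordinates: {missing[:10]}")
    out = Path(out)
    xs = [coords[s][0] for s in result.spot_ids]
    ys = [coords[s][1] for s in result.spot_ids]
    x0, y0 = min(xs), min(ys)
    width = 2 * _MARGIN + (max(xs) - x0 + 1) * _CELL
    height = 2 * _MARGIN + (max(ys) - y0 + 1) * _CELL
    r = spec.glyph_radius * _CELL

    def hexc(c: tuple[float, float, float]) -> str:
        return "#%02x%02x%02x" % tuple(int(round(v * 255)) for v in c)

    body = []
    for i, spot in enumerate(result.spot_ids):
        x, y = coords[spot]
        cx = _MARGIN + (x - x0 + 0.5) * _CELL
        cy = _MARGIN + (y - y0 + 0.5) * _CELL  # SVG y grows downward: row 1 on top
        props = result.proportions[i]
        body.append(f'<g class="spot" data-spot="{spot}">')
        angles = pie_angles(props)
        for j, (a0, a1) in enumerate(angles):
            color = hexc(cluster_colors[j + 1])
            share = f"{props[j]:.4f}"
            if a1 - a0 >= 2 * math.pi - 1e-9:
                body.append(
                    f'<circle class="slice" cx="{_fmt(cx)}" cy="{_fmt(cy)}" '
                    f'r="{_fmt(r)}" fill="{color}">'
                    f"<title>cluster {j + 1}: {share}</title></circle>"
                )
            elif a1 - a0 > 1e-9:
                body.append(
                    f'<path class="slice" d="{_wedge_path(cx, cy, r, a0, a1)}" '
                    f'fill="{color}"><title>cluster {j + 1}: {share}</title></path>'
                )
        body.append("</g>")
    _write_figure(out, width, height, body, spec)


def _write_figure(
    out: Path, width: float, height: float, body: list[str], spec: RenderSpec
) -> None:
    svg = _svg_document(width, height, body)
    if out.suffix.lower() == ".png":
        _rasterize(svg, out, width, height, spec)
    else:
        out.write_text(svg)


def _rasterize(svg: str, out: Path, width: float, height: float, spec: RenderSpec) -> None:
    # lightweight raster: draw the already-computed primitives with matplotlib
    import io as _io
    import re

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle, PathPatch
    from matplotlib.path import Path as MplPath
    from matplotlib.lines import Line2D

    fig, ax = plt.subplots(
        figsize=(width / spec.figure_dpi, height / spec.figure_dpi),
        dpi=spec.figure_dpi,
    )
    ax.set_xlim(0, width)
    ax.set_ylim(height, 0)
    ax.axis("off")
    for m in re.finditer(r"<circle[^>]*cx=\"([^\"]+)\" cy=\"([^\"]+)\" r=\"([^\"]+)\" fill=\"([^\"]+)\"", svg):
        cx, cy, r, color = float(m[1]), float(m[2]), float(m[3]), m[4]
        ax.add_patch(Circle((cx, cy), r, facecolor=color, edgecolor="none"))
    for m in re.finditer(r"<path[^>]*d=\"([^\"]+)\" fill=\"([^\"]+)\"", svg):
        d, color = m[1], m[2]
        verts, codes = _parse_wedge(d)
        ax.add_patch(PathPatch(MplPath(verts, codes), facecolor=color, edgecolor="none"))
    for m in re.finditer(
        r"<line[^>]*x1=\"([^\"]+)\" y1=\"([^\"]+)\" x2=\"([^\"]+)\" y2=\"([^\"]+)\"[^>]*stroke-opacity=\"([^\"]+)\"",
        svg,
    ):
        ax.add_line(
            Line2D(
                [float(m[1]), float(m[3])],
                [float(m[2]), float(m[4])],
                color="#333333",
                alpha=float(m[5]),
                linewidth=2,
            )
        )
    buf = _io.BytesIO()
    fig.savefig(buf, format="png", dpi=spec.figure_dpi)
    plt.close(fig)
    out.write_bytes(buf.getvalue())


def _parse_wedge(d: str):
    import re

    import numpy as np
    from matplotlib.path import Path as MplPath

    nums = [float(x) for x in re.findall(r"-?\d+\.?\d*", d)]
    cx, cy, x0, y0 = nums[0], nums[1], nums[2], nums[3]
    r, x1, y1 = nums[4], nums[7], nums[8]
    a0 = math.atan2(x0 - cx, cy - y0)
    a1 = math.atan2(x1 - cx, cy - y1)
    if a1 <= a0:
        a1 += 2 * math.pi
    thetas = np.linspace(a0, a1, 64)
    arc = [(cx + r * math.sin(t), cy - r * math.cos(t)) for t in thetas]
    verts = [(cx, cy), (x0, y0), *arc, (cx, cy)]
    codes = [MplPath.MOVETO, MplPath.LINETO] + [MplPath.LINETO] * len(arc) + [
        MplPath.CLOSEPOLY
    ]
    return verts, codes


def export_report(
    graph: ClusterGraph,
    results: Sequence[SimilarityResult],
    coords: SpotCoordinates,
    mrc: MultiResolutionClustering,
    out_dir: str | Path,
    params: Mapping | None = None,
    spec: RenderSpec = RenderSpec(),
) -> dict:
    """Write the full static report and return its manifest.

    Emits the cluster graph as SVG, DOT and JSON, one array-plot SVG and one
    score TSV per resolution, the assignment table, and ``manifest.json``
    listing every file with a SHA-256 checksum plus the parameters used, so
    a rerun can be verified byte-for-byte.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    errors: dict[str, str] = {}

    def emit(name: str, writer) -> None:
        path = out_dir / name
        try:
            writer(path)
        except Exception as exc:  # report per-file, keep going
            errors[name] = str(exc)
            return
        files[name] = hashlib.sha256(path.read_bytes()).hexdigest()

    emit("cluster_graph.svg", lambda p: render_cluster_graph(graph, spec, p))
    emit("cluster_graph.dot", lambda p: p.write_text(graph.to_dot()))
    emit("cluster_graph.json", lambda p: p.write_text(graph.to_json()))
    for result in results:
        label = result.resolution_label
        colors = graph.colors_at(label)
        emit(
            f"array_{label}.svg",
            lambda p, result=result, colors=colors: render_array_plot(
                result, coords, colors, spec, p
            ),
        )
        emit(
            f"scores_{label}.tsv",
            lambda p, result=result: result.to_dataframe().to_csv(p, sep="\t"),
        )
    emit("assignments.tsv", lambda p: mrc.to_dataframe().to_csv(p, sep="\t"))

    manifest = {
        "files": dict(sorted(files.items())),
        "parameters": dict(params or {}),
        "resolutions": list(graph.resolution_order),
        "edge_threshold": graph.threshold_applied,
    }
    if errors:
        manifest["errors"] = errors
        logger.error("export_report: %d files failed: %s", len(errors), errors)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
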
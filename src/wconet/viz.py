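"""Network rendering with the co-occurrence visual encoding.

Encoding contract: point (node) area is affine in degree centrality within
declared bounds, line (edge) opacity is affine in the Spearman coefficient
on [rho_min, max rho] — darker lines mean stronger co-occurrence — and the
legend lists cluster labels in descending order of cluster size. Clusters
are laid out in disjoint bounding regions (each cluster detached from the
others), with a seeded force-directed placement inside each region.

SVG is the canonical output: nodes are ``<circle>`` elements with explicit
radii, edges are ``<line>`` elements with explicit ``stroke-opacity``, so
the encoding is machine-checkable, and no timestamps are emitted, so the
same seed yields byte-identical files. PNG is rendered from the same layout
and style via matplotlib.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

__all__ = [
    "LayoutSpec",
    "StyleSpec",
    "compute_layout",
    "load_translations",
    "render_network",
    "render_svg",
    "render_png",
]

logger = logging.getLogger(__name__)

# Qualitative palette for cluster colours, cycled by cluster rank.
_PALETTE = [
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
    "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
]


@dataclass
class LayoutSpec:
    positions: dict[str, tuple[float, float]]
    cluster_boxes: dict[int, tuple[float, float, float, float]]  # x0,y0,x1,y1
    seed: int
    algorithm: str = "force-directed"

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "algorithm": self.algorithm,
                    "seed": self.seed,
                    "positions": {w: list(p) for w, p in self.positions.items()},
                    "cluster_boxes": {
                        str(k): list(v) for k, v in self.cluster_boxes.items()
                    },
                },
                fh,
                indent=2,
                sort_keys=True,
            )


@dataclass
class StyleSpec:
    """Affine size/opacity maps with declared bounds.

    ``node_area_bounds`` are the marker areas (in squared canvas units)
    assigned to the minimum and maximum degree; ``edge_opacity_bounds`` are
    the opacities assigned to rho_min and the maximum retained rho. Both
    maps are strictly increasing.
    """

    node_area_bounds: tuple[float, float] = (60.0, 1200.0)
    edge_opacity_bounds: tuple[float, float] = (0.15, 1.0)
    rho_min: float = 0.1
    translations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.node_area_bounds[0] < self.node_area_bounds[1]:
            raise ValueError("node_area_bounds must be increasing")
        lo, hi = self.edge_opacity_bounds
        if not (0.0 < lo < hi <= 1.0):
            raise ValueError("edge_opacity_bounds must satisfy 0 < lo < hi <= 1")

    def node_area(self, degree: int, deg_min: int, deg_max: int) -> float:
        a0, a1 = self.node_area_bounds
        if deg_max == deg_min:
            return (a0 + a1) / 2.0
        return a0 + (a1 - a0) * (degree - deg_min) / (deg_max - deg_min)

    def edge_opacity(self, rho: float, rho_max: float) -> float:
        o0, o1 = self.edge_opacity_bounds
        if rho_max <= self.rho_min:
            return o1
        t = (rho - self.rho_min) / (rho_max - self.rho_min)
        return o0 + (o1 - o0) * min(max(t, 0.0), 1.0)

    def display_label(self, lemma: str) -> str:
        label = self.translations.get(lemma)
        if label is None and self.translations:
            logger.debug("no translation for %r; using lemma", lemma)
        return label if label is not None else lemma

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "node_area_bounds": list(self.node_area_bounds),
                    "edge_opacity_bounds": list(self.edge_opacity_bounds),
                    "rho_min": self.rho_min,
                    "translations": self.translations,
                },
                fh,
                indent=2,
                sort_keys=True,
            )


def compute_layout(
    graph: nx.Graph, clusters, seed: int = 1, cell: float = 260.0, margin: float = 35.0
) -> LayoutSpec:
    """Place ranked clusters in disjoint grid cells.

    Clusters occupy cells of a square grid in rank order (largest first,
    top-left); node positions within each cluster come from a seeded
    force-directed (Fruchterman–Reingold) iteration rescaled into the cell
    interior, so bounding boxes of distinct clusters never overlap. Same
    seed and same graph give identical coordinates.
    """
    ranked = sorted(clusters, key=lambda c: c.rank or 0)
    n_cols = max(1, math.ceil(math.sqrt(len(ranked))))
    positions: dict[str, tuple[float, float]] = {}
    boxes: dict[int, tuple[float, float, float, float]] = {}
    for idx, cluster in enumerate(ranked):
        row, col = divmod(idx, n_cols)
        x0, y0 = col * cell, row * cell
        boxes[cluster.rank] = (x0, y0, x0 + cell, y0 + cell)
        cx, cy = x0 + cell / 2.0, y0 + cell / 2.0
        members = sorted(cluster.members)
        if len(members) == 1:
            positions[members[0]] = (round(cx, 4), round(cy, 4))
            continue
        sub = graph.subgraph(members)
        raw = nx.spring_layout(sub, seed=seed + (cluster.rank or 0), dim=2)
        xs = [p[0] for p in raw.values()]
        ys = [p[1] for p in raw.values()]
        span_x = max(xs) - min(xs) or 1.0
        span_y = max(ys) - min(ys) or 1.0
        half = cell / 2.0 - margin
        for w, (px, py) in raw.items():
            nx_ = cx + (2.0 * (px - min(xs)) / span_x - 1.0) * half
            ny_ = cy + (2.0 * (py - min(ys)) / span_y - 1.0) * half
            positions[w] = (round(nx_, 4), round(ny_, 4))
    return LayoutSpec(positions, boxes, seed=seed)


def load_translations(path: str | Path) -> dict[str, str]:
    """Two-column CSV (lemma, display label) for node display text.

    Lemmas absent from the table fall back to the lemma itself at render
    time; duplicate lemma rows are an error naming the lemma.
    """
    table: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.reader(fh), 1):
            if not row or (lineno == 1 and row[0].lower() in ("lemma", "word")):
                continue
            if len(row) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(row)}")
            lemma, display = row[0].strip(), row[1].strip()
            if lemma in table:
                raise ValueError(f"duplicate translation for lemma {lemma!r}")
            table[lemma] = display
    return table


def _fmt(x: float) -> str:
    return f"{x:.4f}".rstrip("0").rstrip(".")


def render_svg(
    graph: nx.Graph,
    clusters,
    layout: LayoutSpec,
    style: StyleSpec,
    path: str | Path,
    cluster_labels: dict[int, str] | None = None,
) -> None:
    """Write the network as a standalone SVG file.

    Deterministic: elements are emitted in sorted order and the file
    carries no timestamps or environment-dependent content.
    """
    degrees = {w: int(d) for w, d in graph.degree()}
    deg_min, deg_max = min(degrees.values()), max(degrees.values())
    rhos = [d["rho"] for _, _, d in graph.edges(data=True)]
    rho_max = max(rhos)
    cluster_of = {w: c.rank for c in clusters for w in c.members}
    colors = {
        c.rank: _PALETTE[((c.rank or 1) - 1) % len(_PALETTE)] for c in clusters
    }
    labels = cluster_labels or {}

    xs = [p[0] for p in layout.positions.values()]
    ys = [p[1] for p in layout.positions.values()]
    pad = 60.0
    legend_w = 260.0
    x0, y0 = min(xs) - pad, min(ys) - pad
    width = (max(xs) - min(xs)) + 2 * pad + legend_w
    height = max((max(ys) - min(ys)) + 2 * pad, 40.0 + 22.0 * len(list(clusters)))

    def tx(p: tuple[float, float]) -> tuple[float, float]:
        return (p[0] - x0, p[1] - y0)

    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{_fmt(width)}" '
        f'height="{_fmt(height)}" viewBox="0 0 {_fmt(width)} {_fmt(height)}">',
        '<g id="edges" stroke="#202020" stroke-width="1.5">',
    ]
    for a, b, data in sorted(graph.edges(data=True), key=lambda e: (e[0], e[1])):
        xa, ya = tx(layout.positions[a])
        xb, yb = tx(layout.positions[b])
        op = style.edge_opacity(data["rho"], rho_max)
        parts.append(
            f'<line x1="{_fmt(xa)}" y1="{_fmt(ya)}" x2="{_fmt(xb)}" y2="{_fmt(yb)}" '
            f'stroke-opacity="{op:.4f}"/>'
        )
    parts.append("</g>")
    parts.append('<g id="nodes">')
    for w in sorted(graph.nodes):
        x, y = tx(layout.positions[w])
        area = style.node_area(degrees[w], deg_min, deg_max)
        r = math.sqrt(area / math.pi)
        parts.append(
            f'<circle id="node-{w}" cx="{_fmt(x)}" cy="{_fmt(y)}" r="{r:.4f}" '
            f'fill="{colors[cluster_of[w]]}" fill-opacity="0.85"/>'
        )
    parts.append("</g>")
    parts.append('<g id="labels" font-family="sans-serif" font-size="11">')
    for w in sorted(graph.nodes):
        x, y = tx(layout.positions[w])
        parts.append(
            f'<text x="{_fmt(x)}" y="{_fmt(y - 6)}" text-anchor="middle">'
            f"{style.display_label(w)}</text>"
        )
    parts.append("</g>")
    # Legend: cluster labels in descending order of cluster size (rank order).
    parts.append('<g id="legend" font-family="sans-serif" font-size="13">')
    lx = width - legend_w + 20.0
    ly = 30.0
    parts.append(
        f'<text x="{_fmt(lx)}" y="{_fmt(ly)}" font-weight="bold">Clusters</text>'
    )
    for c in sorted(clusters, key=lambda c: c.rank or 0):
        ly += 22.0
        text = labels.get(c.rank, f"cluster {c.rank}")
        parts.append(
            f'<circle cx="{_fmt(lx + 6)}" cy="{_fmt(ly - 4)}" r="6" '
            f'fill="{colors[c.rank]}"/>'
        )
        parts.append(
            f'<text class="legend-entry" x="{_fmt(lx + 20)}" y="{_fmt(ly)}">'
            f"{c.rank}. {text} (n={c.size})</text>"
        )
    parts.append("</g>")
    parts.append("</svg>")
    Path(path).write_text("\n".join(parts) + "\n", encoding="utf-8")


def render_png(
    graph: nx.Graph,
    clusters,
    layout: LayoutSpec,
    style: StyleSpec,
    path: str | Path,
    cluster_labels: dict[int, str] | None = None,
) -> None:
    """Raster rendering of the same layout and style via matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    degrees = {w: int(d) for w, d in graph.degree()}
    deg_min, deg_max = min(degrees.values()), max(degrees.values())
    rho_max = max(d["rho"] for _, _, d in graph.edges(data=True))
    cluster_of = {w: c.rank for c in clusters for w in c.members}
    colors = {c.rank: _PALETTE[((c.rank or 1) - 1) % len(_PALETTE)] for c in clusters}
    labels = cluster_labels or {}

    fig, ax = plt.subplots(figsize=(10, 8))
    for a, b, data in graph.edges(data=True):
        xa, ya = layout.positions[a]
        xb, yb = layout.positions[b]
        ax.plot(
            [xa, xb], [ya, yb], color="#202020",
            alpha=style.edge_opacity(data["rho"], rho_max), lw=1.2, zorder=1,
        )
    for w in graph.nodes:
        x, y = layout.positions[w]
        ax.scatter(
            [x], [y], s=style.node_area(degrees[w], deg_min, deg_max) / 2.0,
            color=colors[cluster_of[w]], alpha=0.85, zorder=2,
        )
        ax.annotate(
            style.display_label(w), (x, y), textcoords="offset points",
            xytext=(0, 6), ha="center", fontsize=7, zorder=3,
        )
    handles = [
        plt.Line2D(
            [], [], marker="o", ls="", color=colors[c.rank],
            label=f"{c.rank}. {labels.get(c.rank, f'cluster {c.rank}')} (n={c.size})",
        )
        for c in sorted(clusters, key=lambda c: c.rank or 0)
    ]
    ax.legend(handles=handles, loc="upper left", bbox_to_anchor=(1.01, 1.0))
    ax.invert_yaxis()
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def render_network(
    graph: nx.Graph,
    clusters,
    layout: LayoutSpec,
    style: StyleSpec,
    out_dir: str | Path,
    cluster_labels: dict[int, str] | None = None,
    basename: str = "network",
) -> tuple[Path, Path]:
    """Write SVG (canonical) and PNG renderings plus layout/style JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    svg = out_dir / f"{basename}.svg"
    png = out_dir / f"{basename}.png"
    render_svg(graph, clusters, layout, style, svg, cluster_labels)
    render_png(graph, clusters, layout, style, png, cluster_labels)
    layout.to_json(out_dir / f"{basename}_layout.json")
    style.to_json(out_dir / f"{basename}_style.json")
    return svg, png
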
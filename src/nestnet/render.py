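"""Deterministic SVG rendering of laid-out nested networks.

Containers are drawn as circles beneath their members (outermost first, so
deeper content paints on top), leaf edges as thin lines, association edges
with width proportional to their aggregated weight, and nodes as filled
circles whose fill and radius come from the ``color`` and ``size`` node
attributes.  Layout coordinates are Cartesian (y up); SVG's y axis points
down, so the exporter flips y — without this the picture would be silently
mirrored.  Output bytes are a pure function of the inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

from .core import ASSOCIATION, LEAF, GraphError, HierGraph
from .layout import LayoutState

__all__ = ["RenderSpec", "export_svg"]


@dataclass
class RenderSpec:
    """Visual contract of the exported picture."""

    width: int = 800
    height: int = 600
    margin: int = 40
    node_size: float = 8.0
    node_color: str = "#6699CC"
    container_stroke: str = "#888888"
    container_fill: str = "#F2F2F2"
    edge_color: str = "#BBBBBB"
    association_color: str = "#555555"
    #: stroke width of an association edge of weight 1.0
    association_width_scale: float = 8.0
    flip_y: bool = True
    draw_labels: bool = True

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("canvas dimensions must be positive")


def _fmt(x: float) -> str:
    return f"{x:.2f}"


def export_svg(
    g: HierGraph,
    state: LayoutState,
    spec: RenderSpec = RenderSpec(),
    path: Union[str, Path, None] = None,
) -> str:
    """Render the graph; return the SVG text (and write it when given a path)."""
    ids = g.node_ids()
    missing = [nid for nid in ids if nid not in state.positions]
    if missing:
        raise GraphError(f"layout missing coordinates for: {missing[:5]}")

    xs = [state.positions[n][0] for n in ids]
    ys = [state.positions[n][1] for n in ids]
    pads = [state.radii.get(n, 0.0) for n in ids]
    lo_x = min(x - p for x, p in zip(xs, pads))
    hi_x = max(x + p for x, p in zip(xs, pads))
    lo_y = min(y - p for y, p in zip(ys, pads))
    hi_y = max(y + p for y, p in zip(ys, pads))
    span_x = max(hi_x - lo_x, 1e-9)
    span_y = max(hi_y - lo_y, 1e-9)
    scale = min(
        (spec.width - 2 * spec.margin) / span_x,
        (spec.height - 2 * spec.margin) / span_y,
    )

    def to_canvas(nid: str) -> tuple[float, float]:
        x, y = state.positions[nid]
        cx = spec.margin + (x - lo_x) * scale
        cy = (y - lo_y) * scale
        if spec.flip_y:
            cy = spec.height - spec.margin - cy
        else:
            cy = spec.margin + cy
        return cx, cy

    parts: list[str] = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{spec.width}" '
        f'height="{spec.height}" viewBox="0 0 {spec.width} {spec.height}">',
    ]

    # containers first (beneath members), outermost first
    containers = sorted(g.container_ids(), key=lambda c: (g.depth(c), c))
    for cid in containers:
        cx, cy = to_canvas(cid)
        r = state.radii.get(cid, 0.0) * scale
        parts.append(
            f'<circle class="container" id="{cid}" cx="{_fmt(cx)}" '
            f'cy="{_fmt(cy)}" r="{_fmt(r)}" fill="{spec.container_fill}" '
            f'stroke="{spec.container_stroke}" stroke-dasharray="4,2"/>'
        )

    for e in g.edges(layer=LEAF):
        (x1, y1), (x2, y2) = to_canvas(e.u), to_canvas(e.v)
        parts.append(
            f'<line x1="{_fmt(x1)}" y1="{_fmt(y1)}" x2="{_fmt(x2)}" '
            f'y2="{_fmt(y2)}" stroke="{spec.edge_color}" stroke-width="1"/>'
        )
    for e in g.edges(layer=ASSOCIATION):
        (x1, y1), (x2, y2) = to_canvas(e.u), to_canvas(e.v)
        w = max(spec.association_width_scale * e.weight, 0.5)
        parts.append(
            f'<line class="association" x1="{_fmt(x1)}" y1="{_fmt(y1)}" '
            f'x2="{_fmt(x2)}" y2="{_fmt(y2)}" '
            f'stroke="{spec.association_color}" stroke-width="{_fmt(w)}"/>'
        )

    for nid in g.leaf_ids():
        rec = g.node(nid)
        cx, cy = to_canvas(nid)
        size = float(rec.attrs.get("size", spec.node_size))
        color = str(rec.attrs.get("color", spec.node_color))
        parts.append(
            f'<circle class="node" id="{nid}" cx="{_fmt(cx)}" cy="{_fmt(cy)}" '
            f'r="{_fmt(size / 2)}" fill="{color}" stroke="#333333"/>'
        )
        if spec.draw_labels and "label" in rec.attrs:
            parts.append(
                f'<text x="{_fmt(cx + size / 2 + 2)}" y="{_fmt(cy + 3)}" '
                f'font-size="9" font-family="sans-serif">'
                f"{rec.attrs['label']}</text>"
            )
    parts.append("</svg>")
    text = "\n".join(parts) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
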
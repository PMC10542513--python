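"""Static SVG rendering of 2D layouts.

Nodes are drawn as line segments between their two end points (round
caps keep zero-length segments visible as dots); edges optionally as
thin lines between the linked node ends.  Output is deterministic for
fixed inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .engine import Layout2D
from .graph import Handle, VariationGraph

__all__ = ["RenderOptions", "render_svg"]

_NODE_COLOR = "#3465a4"
_MEMBER_COLOR = "#cc0000"
_EDGE_COLOR = "#000000"


@dataclass(frozen=True)
class RenderOptions:
    size: float = 800.0
    stroke_width: float = 2.0
    color_path: str | None = None  # highlight members of this path
    draw_edges: bool = True
    margin: float = 10.0

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError("canvas size must be > 0")


def _edge_endpoint_row(handle: Handle, side: str, id_to_idx: dict[int, int]) -> int:
    """Row of the node end an edge attaches to.

    Leaving a forward node (or entering it on its reverse traversal)
    happens at its sequence-end end; mirrored for reverse strands.
    """
    k = id_to_idx[handle.node_id]
    if side == "out":
        return 2 * k if handle.is_reverse else 2 * k + 1
    return 2 * k + 1 if handle.is_reverse else 2 * k


def render_svg(
    graph: VariationGraph, layout: Layout2D, options: RenderOptions | None = None
) -> str:
    """Render a 2D layout as a standalone SVG document string."""
    options = options or RenderOptions()
    coords = layout.coords
    if not math.isfinite(float(coords.sum())):
        raise FloatingPointError("layout contains non-finite coordinates")

    xmin, ymin = coords.min(axis=0)
    xmax, ymax = coords.max(axis=0)
    span = max(xmax - xmin, ymax - ymin, 1e-12)
    scale = (options.size - 2 * options.margin) / span

    def mapped(row: int) -> tuple[float, float]:
        x = (coords[row, 0] - xmin) * scale + options.margin
        y = (coords[row, 1] - ymin) * scale + options.margin
        return x, y

    width = (xmax - xmin) * scale + 2 * options.margin
    height = (ymax - ymin) * scale + 2 * options.margin

    members: set[int] = set()
    if options.color_path is not None:
        members = {s.node_id for s in graph.path_by_name(options.color_path).steps}

    out = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        '<svg xmlns="http://www.w3.org/2000/svg" width="{:.3f}" height="{:.3f}" '
        'viewBox="0 0 {:.3f} {:.3f}">'.format(width, height, width, height),
    ]

    if options.draw_edges:
        out.append('<g class="edges" stroke="{}" stroke-width="{:.3f}">'.format(
            _EDGE_COLOR, options.stroke_width * 0.25
        ))
        for edge in graph.edges:
            x1, y1 = mapped(_edge_endpoint_row(edge.src, "out", layout.id_to_idx))
            x2, y2 = mapped(_edge_endpoint_row(edge.dst, "in", layout.id_to_idx))
            out.append(
                '<line x1="{:.3f}" y1="{:.3f}" x2="{:.3f}" y2="{:.3f}"/>'.format(
                    x1, y1, x2, y2
                )
            )
        out.append("</g>")

    out.append(
        '<g class="nodes" stroke-width="{:.3f}" stroke-linecap="round">'.format(
            options.stroke_width
        )
    )
    for k, nid in enumerate(layout.node_ids):
        x1, y1 = mapped(2 * k)
        x2, y2 = mapped(2 * k + 1)
        color = _MEMBER_COLOR if nid in members else _NODE_COLOR
        out.append(
            '<line x1="{:.3f}" y1="{:.3f}" x2="{:.3f}" y2="{:.3f}" stroke="{}"/>'.format(
                x1, y1, x2, y2, color
            )
        )
    out.append("</g>")
    out.append("</svg>")
    return "\n".join(out) + "\n"
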
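"""Deterministic SVG rendering of switch-analysis diagrams.

The diagram mirrors the standard traffic-analysis layout: compartments as
labelled nodes on a circle, adjacency edges as solid lines, non-adjacent
compared pairs as dashed lines, and a pie chart per category whose segments
are proportional to (unique to phenotype 1, shared, unique to phenotype 2).
The ubiquitous (A-type) pie sits top-left; edge (B) pies sit on edge
midpoints; per-compartment (U) pies sit beside their node; non-adjacent
(N2) pies sit on the dashed connector.  Each pie is annotated with J and p.

Output is plain SVG assembled from fixed-precision strings, so identical
input yields byte-identical files.
"""

from __future__ import annotations

import math
from typing import Sequence

from .traffic import CompartmentNetwork, SwitchComparison

__all__ = ["render_switch_svg"]

_COL_1 = "#d95f02"  # unique to phenotype 1
_COL_SHARED = "#7570b3"
_COL_2 = "#1b9e77"  # unique to phenotype 2


def _fmt(x: float) -> str:
    return f"{x:.2f}"


def _pie(cx: float, cy: float, r: float, counts: tuple[int, int, int]) -> list[str]:
    """Pie chart segments for (unique_1, shared, unique_2); skips zero slices."""
    total = sum(counts)
    parts: list[str] = []
    if total == 0:
        return parts
    colors = (_COL_1, _COL_SHARED, _COL_2)
    nonzero = [(c, col) for c, col in zip(counts, colors) if c > 0]
    if len(nonzero) == 1:
        parts.append(
            f'<circle cx="{_fmt(cx)}" cy="{_fmt(cy)}" r="{_fmt(r)}" '
            f'fill="{nonzero[0][1]}" stroke="black" stroke-width="0.5"/>'
        )
        return parts
    angle = -90.0  # start at 12 o'clock
    for count, color in nonzero:
        sweep = 360.0 * count / total
        a0, a1 = math.radians(angle), math.radians(angle + sweep)
        x0, y0 = cx + r * math.cos(a0), cy + r * math.sin(a0)
        x1, y1 = cx + r * math.cos(a1), cy + r * math.sin(a1)
        large = 1 if sweep > 180 else 0
        parts.append(
            f'<path d="M {_fmt(cx)} {_fmt(cy)} L {_fmt(x0)} {_fmt(y0)} '
            f'A {_fmt(r)} {_fmt(r)} 0 {large} 1 {_fmt(x1)} {_fmt(y1)} Z" '
            f'fill="{color}" stroke="black" stroke-width="0.5"/>'
        )
        angle += sweep
    return parts


def _p_text(p: float | None) -> str:
    if p is None:
        return "p=n/a"
    if p < 1e-3:
        return f"p={p:.1e}"
    return f"p={p:.3f}"


def _annotate(x: float, y: float, comp: SwitchComparison) -> str:
    return (
        f'<text x="{_fmt(x)}" y="{_fmt(y)}" font-size="9" '
        f'font-family="sans-serif" text-anchor="middle">'
        f"J={comp.jtc:.2f} {_p_text(comp.p_value)}</text>"
    )


def render_switch_svg(
    network: CompartmentNetwork,
    comparisons: Sequence[SwitchComparison],
    title: str = "",
    width: int = 640,
    height: int = 480,
) -> str:
    """Render a switch analysis as an SVG document string.

    Categories whose three-way counts are all zero are omitted.  Layout is
    a fixed circular embedding of the compartments, so the output is a pure
    function of its inputs.
    """
    comps = network.compartments
    cx, cy = width / 2.0, height / 2.0 + 20
    radius = min(width, height) / 2.0 - 90
    pos = {}
    for i, c in enumerate(comps):
        a = -math.pi / 2 + 2 * math.pi * i / len(comps)
        pos[c] = (cx + radius * math.cos(a), cy + radius * math.sin(a))

    by_cat = {c.category: c for c in comparisons}
    body: list[str] = []
    if title:
        body.append(
            f'<text x="{_fmt(width / 2)}" y="18" font-size="13" '
            f'font-family="sans-serif" text-anchor="middle">{title}</text>'
        )

    # dashed connectors for compared non-adjacent pairs, then solid edges
    for (a, b) in network.nonadjacent_pairs():
        comp = by_cat.get(f"N2@{a}|{b}")
        if comp is None or sum(comp.counts) == 0:
            continue
        (xa, ya), (xb, yb) = pos[a], pos[b]
        body.append(
            f'<line x1="{_fmt(xa)}" y1="{_fmt(ya)}" x2="{_fmt(xb)}" y2="{_fmt(yb)}" '
            'stroke="#888888" stroke-width="1" stroke-dasharray="5,4"/>'
        )
    for (a, b) in network.edges:
        (xa, ya), (xb, yb) = pos[a], pos[b]
        body.append(
            f'<line x1="{_fmt(xa)}" y1="{_fmt(ya)}" x2="{_fmt(xb)}" y2="{_fmt(yb)}" '
            'stroke="black" stroke-width="1.5"/>'
        )

    # nodes and labels
    for c in comps:
        x, y = pos[c]
        body.append(
            f'<circle cx="{_fmt(x)}" cy="{_fmt(y)}" r="5" fill="white" '
            'stroke="black" stroke-width="1.2"/>'
        )
        body.append(
            f'<text x="{_fmt(x)}" y="{_fmt(y - 10)}" font-size="11" '
            f'font-family="sans-serif" text-anchor="middle">{c}</text>'
        )

    # A-type pie, top-left
    a_comp = by_cat.get("A")
    if a_comp is not None and sum(a_comp.counts) > 0:
        body.extend(_pie(70, 70, 34, a_comp.counts))
        body.append(
            '<text x="70.00" y="22.00" font-size="10" font-family="sans-serif" '
            'text-anchor="middle">A (ubiquitous)</text>'
        )
        body.append(_annotate(70, 120, a_comp))

    # B pies on edge midpoints
    for (a, b) in network.edges:
        comp = by_cat.get(f"B@{a}-{b}") or by_cat.get(f"B@{b}-{a}")
        if comp is None or sum(comp.counts) == 0:
            continue
        (xa, ya), (xb, yb) = pos[a], pos[b]
        mx, my = (xa + xb) / 2, (ya + yb) / 2
        body.extend(_pie(mx, my, 20, comp.counts))
        body.append(_annotate(mx, my + 34, comp))

    # U pies beside their node (pushed outward from the centre)
    for c in comps:
        comp = by_cat.get(f"U@{c}")
        if comp is None or sum(comp.counts) == 0:
            continue
        x, y = pos[c]
        dx, dy = x - cx, y - cy
        norm = math.hypot(dx, dy) or 1.0
        ux, uy = x + 40 * dx / norm, y + 40 * dy / norm
        body.extend(_pie(ux, uy, 13, comp.counts))
        body.append(_annotate(ux, uy + 26, comp))

    # N2 pies on the dashed connector
    for (a, b) in network.nonadjacent_pairs():
        comp = by_cat.get(f"N2@{a}|{b}")
        if comp is None or sum(comp.counts) == 0:
            continue
        (xa, ya), (xb, yb) = pos[a], pos[b]
        mx, my = 0.35 * xa + 0.65 * xb, 0.35 * ya + 0.65 * yb
        body.extend(_pie(mx, my, 11, comp.counts))
        body.append(_annotate(mx, my + 24, comp))

    doc = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
        f'height="{height}" viewBox="0 0 {width} {height}">',
        '<rect width="100%" height="100%" fill="white"/>',
        *body,
        "</svg>",
    ]
    return "\n".join(doc) + "\n"
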
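"""Circular (chord-diagram) rendering of a rule network to SVG.

Conditions sit as arcs on the outer ring, clockwise from 12 o'clock in
the network's node order, each arc's angular width proportional to the
node weight so that the nodes together cover the full circle (minus a
small gap between nodes).  Connections are drawn as cubic Bezier
curves through the interior; their stroke width and color scale with
the connection score, from thin yellow (weakest displayed score) to
thick red (strongest).  A thin inner ring under each node shows, for
every edge endpoint, the color of the condition on the other side of
the connection.

Output is standalone SVG 1.1 assembled with the stdlib XML tools; the
element ids encode (condition pair, outcome) so the interactive HTML
export can bind edge clicks to rule lookups without a server.
"""
from __future__ import annotations

import json
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

from .network import RuleNetwork, edge_rule_lookup
from .rules import Condition

__all__ = [
    "StyleConfig",
    "CircularLayout",
    "layout_circle",
    "render_svg",
    "render_labels_html",
    "export_interactive",
]

# categorical palette keyed by feature (hue repeats after 20 features)
_PALETTE = [
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
    "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
    "#aec7e8", "#ffbb78", "#98df8a", "#ff9896", "#c5b0d5",
    "#c49c94", "#f7b6d2", "#c7c7c7", "#dbdb8d", "#9edae5",
]


@dataclass(frozen=True)
class StyleConfig:
    size: int = 800
    gap_deg: float = 2.0
    ring_width: float = 26.0
    inner_ring_width: float = 10.0
    w_min: float = 1.0
    w_max: float = 12.0
    label_font: float = 12.0
    palette: tuple[str, ...] = tuple(_PALETTE)
    color_low: str = "#FFFF00"
    color_high: str = "#FF0000"


@dataclass
class NodeSpan:
    condition: Condition
    start: float  # degrees, 0 at 12 o'clock, clockwise
    end: float
    color: str


@dataclass
class EdgeGeom:
    index: int  # index into network.edges
    a_arc: tuple[float, float]  # sub-arc on the first endpoint's span
    b_arc: tuple[float, float]
    width: float
    color: str


@dataclass
class InnerSegment:
    condition: Condition  # the node this segment sits under
    start: float
    end: float
    color: str  # the partner node's color


@dataclass
class CircularLayout:
    size: int
    spans: list[NodeSpan]
    edge_geoms: list[EdgeGeom]
    inner_segments: list[InnerSegment]
    style: StyleConfig
    network: RuleNetwork


def _lerp_color(low: str, high: str, t: float) -> str:
    lo = [int(low[i : i + 2], 16) for i in (1, 3, 5)]
    hi = [int(high[i : i + 2], 16) for i in (1, 3, 5)]
    rgb = [round(a + (b - a) * t) for a, b in zip(lo, hi)]
    return "#{:02X}{:02X}{:02X}".format(*rgb)


def layout_circle(network: RuleNetwork, style: StyleConfig | None = None) -> CircularLayout:
    """Compute angular spans, edge anchors, widths and colors.

    Node angular width is ``weight / total_weight * (360 - n*gap)``;
    within a node's span the incident edges each occupy a sub-arc
    proportional to their share of the node weight, packed in partner
    order clockwise.  Edge color and stroke width interpolate linearly
    between the style's low/high endpoints over the displayed score
    range; a single-valued range maps to the high endpoint.
    """
    style = style or StyleConfig()
    if not network.nodes or not network.edges:
        raise ValueError("cannot lay out an empty network; relax the edge filters")
    conditions = network.node_conditions
    order = {c: i for i, c in enumerate(conditions)}
    weights = dict(network.nodes)
    total_weight = sum(weights.values())
    n = len(conditions)
    avail = 360.0 - n * style.gap_deg
    if avail <= 0:
        raise ValueError("gap too large for the number of nodes")

    feats = sorted({c.feature for c in conditions})
    fcolor = {f: style.palette[i % len(style.palette)] for i, f in enumerate(feats)}

    spans: list[NodeSpan] = []
    cursor = 0.0
    for c in conditions:
        width = weights[c] / total_weight * avail
        spans.append(NodeSpan(c, cursor, cursor + width, fcolor[c.feature]))
        cursor += width + style.gap_deg

    # pack each node's incident edges into sub-arcs, in partner order
    incident: dict[Condition, list[tuple[int, Condition]]] = {c: [] for c in conditions}
    for i, e in enumerate(network.edges):
        incident[e.x].append((i, e.y))
        incident[e.y].append((i, e.x))
    sub_arcs: dict[tuple[int, Condition], tuple[float, float]] = {}
    inner: list[InnerSegment] = []
    for span in spans:
        c = span.condition
        edges_here = sorted(incident[c], key=lambda t: (order[t[1]], t[0]))
        cursor = span.start
        node_w = weights[c]
        for i, partner in edges_here:
            frac = network.edges[i].score / node_w if node_w > 0 else 0.0
            width = frac * (span.end - span.start)
            sub_arcs[(i, c)] = (cursor, cursor + width)
            inner.append(InnerSegment(c, cursor, cursor + width, fcolor[partner.feature]))
            cursor += width

    scores = [e.score for e in network.edges]
    smin, smax = min(scores), max(scores)
    geoms: list[EdgeGeom] = []
    for i, e in enumerate(network.edges):
        t = 1.0 if smax == smin else (e.score - smin) / (smax - smin)
        geoms.append(
            EdgeGeom(
                index=i,
                a_arc=sub_arcs[(i, e.x)],
                b_arc=sub_arcs[(i, e.y)],
                width=style.w_min + t * (style.w_max - style.w_min),
                color=_lerp_color(style.color_low, style.color_high, t),
            )
        )
    return CircularLayout(style.size, spans, geoms, inner, style, network)


def _pt(cx: float, cy: float, r: float, angle_deg: float) -> tuple[float, float]:
    a = math.radians(angle_deg)
    return (cx + r * math.sin(a), cy - r * math.cos(a))


def _fmt(x: float) -> str:
    return f"{x:.3f}"


def _arc_path(cx, cy, r_out, r_in, a0, a1) -> str:
    """Annulus wedge between angles a0..a1 (degrees, clockwise)."""
    large = 1 if (a1 - a0) > 180 else 0
    x0, y0 = _pt(cx, cy, r_out, a0)
    x1, y1 = _pt(cx, cy, r_out, a1)
    x2, y2 = _pt(cx, cy, r_in, a1)
    x3, y3 = _pt(cx, cy, r_in, a0)
    return (
        f"M {_fmt(x0)} {_fmt(y0)} "
        f"A {_fmt(r_out)} {_fmt(r_out)} 0 {large} 1 {_fmt(x1)} {_fmt(y1)} "
        f"L {_fmt(x2)} {_fmt(y2)} "
        f"A {_fmt(r_in)} {_fmt(r_in)} 0 {large} 0 {_fmt(x3)} {_fmt(y3)} Z"
    )


def _safe(text: str) -> str:
    return text.replace(" ", "_")


def edge_id(network: RuleNetwork, i: int) -> str:
    e = network.edges[i]
    return _safe(f"edge--{network.outcome}--{e.x}--{e.y}")


def render_svg(layout: CircularLayout) -> str:
    """Serialize a laid-out network as a standalone SVG document."""
    style = layout.style
    size = layout.size
    cx = cy = size / 2.0
    r_label = size / 2.0 - 10.0
    r_out = r_label - style.label_font * 7  # leave room for labels
    r_in = r_out - style.ring_width
    r_inner_out = r_in - 2.0
    r_inner_in = r_inner_out - style.inner_ring_width
    r_edge = r_inner_in - 2.0

    svg = ET.Element(
        "svg",
        {
            "xmlns": "http://www.w3.org/2000/svg",
            "version": "1.1",
            "width": str(size),
            "height": str(size),
            "viewBox": f"0 0 {size} {size}",
        },
    )
    net = layout.network
    # edges under the rings
    g_edges = ET.SubElement(svg, "g", {"id": "edges", "fill": "none"})
    for geom in layout.edge_geoms:
        a_mid = (geom.a_arc[0] + geom.a_arc[1]) / 2.0
        b_mid = (geom.b_arc[0] + geom.b_arc[1]) / 2.0
        x0, y0 = _pt(cx, cy, r_edge, a_mid)
        x1, y1 = _pt(cx, cy, r_edge, b_mid)
        c0 = _pt(cx, cy, r_edge * 0.25, a_mid)
        c1 = _pt(cx, cy, r_edge * 0.25, b_mid)
        path = (
            f"M {_fmt(x0)} {_fmt(y0)} "
            f"C {_fmt(c0[0])} {_fmt(c0[1])} {_fmt(c1[0])} {_fmt(c1[1])} "
            f"{_fmt(x1)} {_fmt(y1)}"
        )
        e = net.edges[geom.index]
        ET.SubElement(
            g_edges,
            "path",
            {
                "id": edge_id(net, geom.index),
                "class": "edge",
                "d": path,
                "stroke": geom.color,
                "stroke-width": _fmt(geom.width),
                "stroke-opacity": "0.75",
            },
        ).append(_title(f"{e.x} -- {e.y} (score {e.score:g})"))
    # inner ring: partner colors
    g_inner = ET.SubElement(svg, "g", {"id": "inner-ring", "stroke": "none"})
    for seg in layout.inner_segments:
        if seg.end <= seg.start:
            continue
        ET.SubElement(
            g_inner,
            "path",
            {
                "class": "inner-segment",
                "d": _arc_path(cx, cy, r_inner_out, r_inner_in, seg.start, seg.end),
                "fill": seg.color,
            },
        )
    # outer ring: node arcs and labels
    g_nodes = ET.SubElement(svg, "g", {"id": "nodes", "stroke": "#ffffff"})
    for span in layout.spans:
        node = ET.SubElement(
            g_nodes,
            "path",
            {
                "id": _safe(f"node--{span.condition}"),
                "class": "node",
                "d": _arc_path(cx, cy, r_out, r_in, span.start, span.end),
                "fill": span.color,
            },
        )
        node.append(_title(str(span.condition)))
    g_labels = ET.SubElement(
        svg,
        "g",
        {
            "id": "labels",
            "font-family": "sans-serif",
            "font-size": _fmt(style.label_font),
        },
    )
    for span in layout.spans:
        mid = (span.start + span.end) / 2.0
        x, y = _pt(cx, cy, r_out + 6.0, mid)
        rot = mid - 90.0
        anchor = "start"
        if 90.0 < mid < 270.0:  # flip labels on the lower half for readability
            rot += 180.0
            anchor = "end"
        text = ET.SubElement(
            g_labels,
            "text",
            {
                "class": "label",
                "x": _fmt(x),
                "y": _fmt(y),
                "text-anchor": anchor,
                "dominant-baseline": "middle",
                "transform": f"rotate({_fmt(rot)} {_fmt(x)} {_fmt(y)})",
            },
        )
        text.text = str(span.condition)
    return ET.tostring(svg, encoding="unicode", xml_declaration=True)


def _title(text: str) -> ET.Element:
    t = ET.Element("title")
    t.text = text
    return t


def render_labels_html(network: RuleNetwork) -> str:
    """HTML table of the circle's node labels, in circle order."""
    total = network.total_score
    rows = []
    for i, (c, w) in enumerate(network.nodes, start=1):
        share = (w / (2.0 * total) * 100.0) if total > 0 else 0.0
        rows.append(
            f"<tr><td>{i}</td><td>{c.feature}</td><td>{c.value}</td>"
            f"<td>{w:g}</td><td>{share:.2f}%</td></tr>"
        )
    return (
        "<table>\n<thead><tr><th>#</th><th>Feature</th><th>Value</th>"
        "<th>Weight</th><th>Share</th></tr></thead>\n<tbody>\n"
        + "\n".join(rows)
        + ("\n" if rows else "")
        + "</tbody>\n</table>"
    )


_INTERACTIVE_TEMPLATE = """<!DOCTYPE html>
<html>
<head>
<meta charset="utf-8">
<title>Rule network: {outcome}</title>
<style>
body {{ font-family: sans-serif; display: flex; }}
#rules {{ margin-left: 1em; max-width: 30em; }}
.edge {{ cursor: pointer; }}
.edge.selected {{ stroke: #000000; }}
</style>
</head>
<body>
<div id="figure">
{svg}
</div>
<div id="rules"><h3>Rules</h3><p>Click an edge; Ctrl-click to intersect several.</p>
<ul id="rule-list"></ul></div>
<script>
var EDGE_RULES = {sidecar};
var selected = [];
function refresh() {{
  var lists = selected.map(function (id) {{ return EDGE_RULES[id].rules; }});
  var common = lists.length ? lists[0].filter(function (r) {{
    return lists.every(function (l) {{ return l.indexOf(r) >= 0; }});
  }}) : [];
  var ul = document.getElementById('rule-list');
  ul.innerHTML = '';
  common.forEach(function (r) {{
    var li = document.createElement('li');
    li.textContent = r;
    ul.appendChild(li);
  }});
}}
document.querySelectorAll('.edge').forEach(function (el) {{
  el.addEventListener('click', function (ev) {{
    if (!ev.ctrlKey) {{
      selected.forEach(function (id) {{
        document.getElementById(id).classList.remove('selected');
      }});
      selected = [];
    }}
    if (selected.indexOf(el.id) < 0) {{
      selected.push(el.id);
      el.classList.add('selected');
    }}
    refresh();
  }});
}});
</script>
</body>
</html>
"""


def export_interactive(
    network: RuleNetwork, layout: CircularLayout | None = None
) -> tuple[str, dict]:
    """Static interactive HTML plus a JSON sidecar mapping edges to rules.

    The sidecar maps each SVG edge id to the conditions and the full
    text of the contributing rules; the embedded script shows a clicked
    edge's rules and the intersection under Ctrl-multi-select, entirely
    client-side.
    """
    layout = layout or layout_circle(network)
    sidecar: dict[str, dict] = {}
    for i, e in enumerate(network.edges):
        rules = (
            [str(r) for r in edge_rule_lookup(network, e)]
            if network.rules_by_id
            else []
        )
        sidecar[edge_id(network, i)] = {
            "conditions": [str(e.x), str(e.y)],
            "score": e.score,
            "rule_ids": list(e.rule_ids),
            "rules": rules,
        }
    svg = render_svg(layout)
    html = _INTERACTIVE_TEMPLATE.format(
        outcome=network.outcome,
        svg=svg,
        sidecar=json.dumps(sidecar, indent=1, sort_keys=True),
    )
    return html, sidecar
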
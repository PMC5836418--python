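"""Circle-chord diagrams and a static HTML report for a cluster tree.

Each cluster is drawn as a circle diagram: the nucleotides sit on a
circle — position 1 at 12 o'clock, advancing clockwise by 2*pi*(pos-1)/L,
with a tick every 10 nt — and every basepair above a plotting floor is a
straight chord between its two positions, its opacity an affine, monotone
function of the node-conditional pairing probability (probability 1 is
fully opaque).  The constraints accumulated on the node's path are always
drawn and highlighted: pairs constrained present in red, absent in blue.
Conflicting chords literally intersect inside the circle, which is what
makes this layout the natural picture of ensemble multimodality.

The report is fully static: one standalone SVG per node, a single HTML
page laying the nodes out as a collapsible binary tree (details/summary,
no scripts, no network), and a JSON file mirroring the tree serialization.
Rendering is deterministic — all coordinates and opacities are written
with fixed precision — so re-rendering a parsed report.json reproduces the
SVGs byte for byte.
"""

from __future__ import annotations

import html
import json
import os

from .mibp_tree import ClusterTree, tree_to_dict

__all__ = ["circle_diagram_svg", "render_report", "PLOT_FLOOR"]

#: Chords with node-conditional probability below this are omitted.
PLOT_FLOOR = 0.01

_SIZE = 420.0
_RADIUS = 170.0
_CENTER = _SIZE / 2.0


def _fmt(x: float) -> str:
    return f"{x:.3f}"


def _anchor(pos: int, length: int) -> tuple[float, float]:
    """Circle anchor of 1-based position: 12 o'clock start, clockwise."""
    import math

    theta = 2.0 * math.pi * (pos - 1) / length
    return (_CENTER + _RADIUS * math.sin(theta), _CENTER - _RADIUS * math.cos(theta))


def _opacity(p: float) -> float:
    """Affine monotone map: p = 0 -> 0.08 (barely visible), p = 1 -> 1.0."""
    return 0.08 + 0.92 * max(0.0, min(1.0, p))


def circle_diagram_svg(node: dict, sequence: str, floor: float = PLOT_FLOOR) -> str:
    """Standalone SVG circle diagram for one serialized cluster node.

    ``node`` is an entry of the JSON tree (keys ``marginals`` as
    [i, j, p] triples and ``constraints``).  Chords below ``floor`` are
    omitted unless they are constraint pairs, which are always drawn —
    red when constrained present, blue when absent.
    """
    length = len(sequence)
    constrained = {tuple(c["pair"]): c["present"] for c in node["constraints"]}
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{int(_SIZE)}" '
        f'height="{int(_SIZE)}" viewBox="0 0 {int(_SIZE)} {int(_SIZE)}">',
        f'<circle cx="{_fmt(_CENTER)}" cy="{_fmt(_CENTER)}" r="{_fmt(_RADIUS)}" '
        'fill="none" stroke="#cccccc" stroke-width="1"/>',
    ]
    # position ticks every 10 nt
    for pos in range(10, length + 1, 10):
        x, y = _anchor(pos, length)
        xc = _CENTER + (x - _CENTER) * 1.06
        yc = _CENTER + (y - _CENTER) * 1.06
        parts.append(
            f'<line x1="{_fmt(x)}" y1="{_fmt(y)}" x2="{_fmt(xc)}" y2="{_fmt(yc)}" '
            'stroke="#999999" stroke-width="1"/>'
        )
        xt = _CENTER + (x - _CENTER) * 1.14
        yt = _CENTER + (y - _CENTER) * 1.14
        parts.append(
            f'<text x="{_fmt(xt)}" y="{_fmt(yt)}" font-size="9" fill="#666666" '
            f'text-anchor="middle" dominant-baseline="middle">{pos}</text>'
        )
    # plain chords first (ascending (i, j) as serialized), constraints on top
    for i, j, p in node["marginals"]:
        if (i, j) in constrained:
            continue
        if p < floor:
            continue
        (x1, y1), (x2, y2) = _anchor(i, length), _anchor(j, length)
        parts.append(
            f'<line class="bp" x1="{_fmt(x1)}" y1="{_fmt(y1)}" x2="{_fmt(x2)}" '
            f'y2="{_fmt(y2)}" stroke="#222222" stroke-width="1.5" '
            f'stroke-opacity="{_fmt(_opacity(p))}"/>'
        )
    for (i, j), present in sorted(constrained.items()):
        (x1, y1), (x2, y2) = _anchor(i, length), _anchor(j, length)
        color = "#cc0000" if present else "#0033cc"
        cls = "mibp-present" if present else "mibp-absent"
        dash = "" if present else ' stroke-dasharray="5,3"'
        parts.append(
            f'<line class="{cls}" x1="{_fmt(x1)}" y1="{_fmt(y1)}" x2="{_fmt(x2)}" '
            f'y2="{_fmt(y2)}" stroke="{color}" stroke-width="2.5" '
            f'stroke-opacity="1.000"{dash}/>'
        )
    parts.append("</svg>")
    return "\n".join(parts) + "\n"


def _node_label(node: dict) -> str:
    bits = [f"cluster {node['id']}", f"p = {node['probability']:.4f}"]
    bits.append(f"H = {node['entropy_bits']:.3f} bits")
    if node["constraints"]:
        last = node["constraints"][-1]
        i, j = last["pair"]
        state = "present" if last["present"] else "absent"
        bits.append(f"({i},{j}) {state}")
    if node["mibp"] is not None:
        i, j = node["mibp"]
        bits.append(f"MIBP ({i},{j}) sum {node['mibp_mi_sum_bits']:.3f} bits")
    return " | ".join(bits)


def _node_html(node: dict, sequence: str, floor: float) -> str:
    svg = circle_diagram_svg(node, sequence, floor)
    label = html.escape(_node_label(node))
    conflict = ""
    if node["conflicting_pairs"]:
        pairs = ", ".join(f"({i},{j})" for i, j in node["conflicting_pairs"])
        conflict = f"<p>conflicting pairs: {html.escape(pairs)}</p>"
    inner = f"<div class='diagram'>{svg}{conflict}</div>"
    if node["children"]:
        kids = "".join(_node_html(c, sequence, floor) for c in node["children"])
        kids = f"<div class='children'>{kids}</div>"
    else:
        kids = ""
    return (
        f"<details open><summary>{label}</summary>{inner}{kids}</details>"
    )


_CSS = """
body { font-family: sans-serif; margin: 1.5em; }
details { margin-left: 1.6em; border-left: 2px solid #dddddd; padding-left: 0.8em; }
summary { cursor: pointer; font-weight: bold; margin: 0.4em 0; }
.diagram p { margin: 0.2em 0; color: #444444; }
.children { display: block; }
"""


def render_report(
    tree: ClusterTree | dict, out_dir: str, floor: float = PLOT_FLOOR
) -> dict[str, str]:
    """Write report.html, report.json and node_<id>.svg into ``out_dir``.

    Accepts a built :class:`ClusterTree` or an already-serialized tree
    dict (e.g. a parsed report.json), which renders identically.  Returns
    a mapping of artifact names to their paths.
    """
    data = tree_to_dict(tree) if isinstance(tree, ClusterTree) else tree
    os.makedirs(out_dir, exist_ok=True)
    seq = data["sequence"]

    paths = {}
    nodes: list[dict] = []

    def collect(node: dict) -> None:
        nodes.append(node)
        if node["children"]:
            for c in node["children"]:
                collect(c)

    collect(data["root"])
    for node in nodes:
        name = f"node_{node['id']}.svg"
        path = os.path.join(out_dir, name)
        with open(path, "w") as fh:
            fh.write(circle_diagram_svg(node, seq, floor))
        paths[name] = path

    title = data.get("sequence_name") or "RNA ensemble"
    body = _node_html(data["root"], seq, floor)
    html_text = (
        "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
        f"<title>{html.escape(title)} - MIBP clusters</title>"
        f"<style>{_CSS}</style></head><body>"
        f"<h1>{html.escape(title)}</h1>"
        f"<p>{len(seq)} nt, {data['n_samples']} samples, "
        f"{data['n_leaves']} clusters; ensemble entropy "
        f"{data['ensemble_entropy_bits']:.3f} bits, conditional entropy "
        f"{data['conditional_entropy_bits']:.3f} bits.</p>"
        f"{body}</body></html>\n"
    )
    html_path = os.path.join(out_dir, "report.html")
    with open(html_path, "w") as fh:
        fh.write(html_text)
    paths["report.html"] = html_path

    json_path = os.path.join(out_dir, "report.json")
    with open(json_path, "w") as fh:
        json.dump(data, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["report.json"] = json_path
    return paths
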
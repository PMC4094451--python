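"""Static SVG rendering and DOT/GraphML export.

The SVG view follows the visual language of icon-based rule modelling:
species nodes are glyphs (component ellipses, indexed binding-site circles,
tri-state squares, blue bond lines), reactions are small arrowheads pointing
from their reactants toward their products, and every edge is a cubic
Bézier stroked in the category hue — green associations, orange
dissociations, purple transformations — whose saturation rises from the
reactant toward the product end to show direction. Selections thicken and
opacify the involved edges, overlay the rule-side complexes (states, bond
statuses, blue complex-name sublabels) onto the species glyphs, draw a red
border around a searched species and render transformation before/after
pairs in a detached side panel. Output is deterministic: identical inputs
produce byte-identical SVG.

DOT and GraphML exports carry the full bipartite structure (node kind,
rule category, edge role/anchor/occurrence) and reparse to an isomorphic
graph.
"""

from __future__ import annotations

import colorsys
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence
from xml.etree import ElementTree as ET

import networkx as nx

from .glyphs import GlyphMetrics, glyph_plan
from .graph import Edge, EdgeRole, NetworkGraph
from .layout import Layout
from .model import Complex, Model, NetviewError, RuleCategory, TriState
from .query import Overlay, SelectionResult

SVG_NS = "http://www.w3.org/2000/svg"


class RenderError(NetviewError):
    """Layout/graph mismatch or other rendering failure."""


@dataclass(frozen=True)
class StylePalette:
    """Colors and glyph metrics; category hues are freely overridable."""

    category_hue: dict = field(default_factory=lambda: {
        RuleCategory.ASSOCIATION: "#2e9e2e",  # green
        RuleCategory.DISSOCIATION: "#e07818",  # orange
        RuleCategory.TRANSFORMATION: "#8428b4",  # purple
    }, hash=False)
    saturation_range: tuple[float, float] = (0.25, 1.0)
    edge_width: float = 1.6
    base_opacity: float = 0.55
    highlight_opacity: float = 1.0
    highlight_width_mult: float = 2.5
    bond_color: str = "#1f4e9c"
    metrics: GlyphMetrics = field(default_factory=GlyphMetrics)

    @classmethod
    def from_dict(cls, doc: dict) -> "StylePalette":
        """Build a palette from a style JSON object; omitted fields default."""
        kwargs: dict = {}
        if "category_hue" in doc:
            base = cls().category_hue
            for key, color in doc["category_hue"].items():
                base[RuleCategory(key)] = color
            kwargs["category_hue"] = base
        for key in ("saturation_range",):
            if key in doc:
                kwargs[key] = tuple(doc[key])
        for key in ("edge_width", "base_opacity", "highlight_opacity",
                    "highlight_width_mult", "bond_color"):
            if key in doc:
                kwargs[key] = doc[key]
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# colors


def _hex_to_rgb(color: str) -> tuple[float, float, float]:
    color = color.lstrip("#")
    if not re.fullmatch(r"[0-9a-fA-F]{6}", color):
        raise ValueError(f"invalid RGB color {color!r}")
    return tuple(int(color[i:i + 2], 16) / 255.0 for i in (0, 2, 4))


def _rgb_to_hex(rgb: Sequence[float]) -> str:
    return "#" + "".join(f"{round(max(0.0, min(1.0, c)) * 255):02x}" for c in rgb)


def edge_color(category: RuleCategory, t: float,
               style: StylePalette | None = None) -> str:
    """Stroke color at fraction ``t`` along an edge (reactant -> product).

    The hue (and value) are fixed by the category; saturation interpolates
    linearly from the palette's low to high bound in HSV space.
    """
    style = style or StylePalette()
    if not (0.0 <= t <= 1.0):
        raise ValueError(f"t must be within [0, 1], got {t}")
    h, _s, v = colorsys.rgb_to_hsv(*_hex_to_rgb(style.category_hue[category]))
    low, high = style.saturation_range
    return _rgb_to_hex(colorsys.hsv_to_rgb(h, low + t * (high - low), v))


# ---------------------------------------------------------------------------
# Bézier helpers


def _lerp(p, q, t):
    return (p[0] + (q[0] - p[0]) * t, p[1] + (q[1] - p[1]) * t)


def _bezier_split(p0, c1, c2, p1, t0, t1):
    """Control points of the sub-curve of a cubic Bézier on [t0, t1]."""

    def point_and_tangents(t):
        a = _lerp(p0, c1, t)
        b = _lerp(c1, c2, t)
        c = _lerp(c2, p1, t)
        d = _lerp(a, b, t)
        e = _lerp(b, c, t)
        return _lerp(d, e, t), d, e

    q0, d0, e0 = point_and_tangents(t0)
    q1, d1, e1 = point_and_tangents(t1)
    # re-derive inner control points of the restricted curve
    u = (t1 - t0)
    k0 = (q0[0] + (e0[0] - q0[0]) * u, q0[1] + (e0[1] - q0[1]) * u)
    k1 = (q1[0] + (d1[0] - q1[0]) * u, q1[1] + (d1[1] - q1[1]) * u)
    return q0, k0, k1, q1


def _slug(text: str) -> str:
    return re.sub(r"[^A-Za-z0-9_.-]", "_", text)


def _fmt(x: float) -> str:
    return f"{x:.2f}"


# ---------------------------------------------------------------------------
# SVG


def render_svg(graph: NetworkGraph, layout: Layout,
               style: StylePalette | None = None,
               selection: Optional[SelectionResult] = None) -> str:
    """Render the network (optionally with a selection) to SVG text."""
    style = style or StylePalette()
    model = graph.model
    m = style.metrics

    nodes = sorted(graph.species_nodes | graph.reaction_nodes)
    missing = [n for n in nodes if n not in layout.positions]
    if missing:
        raise RenderError("layout misses node(s): " + ", ".join(missing))

    species_order = sorted(graph.species_nodes)
    reaction_order = sorted(graph.reaction_nodes)
    sp_id = {n: f"sp{i}-{_slug(n)}" for i, n in enumerate(species_order)}
    rx_id = {n: f"rx{i}-{_slug(n)}" for i, n in enumerate(reaction_order)}

    plans = {n: glyph_plan(model, n, m) for n in species_order}

    def site_point(species: str, site_index: int) -> tuple[float, float]:
        px, py = layout.positions[species]
        lx, ly = plans[species].site_positions[site_index]
        return (px + lx, py + ly)

    def species_endpoint(edge: Edge) -> tuple[float, float]:
        if edge.anchor is not None and \
                edge.anchor.site_index in plans[edge.species].site_positions:
            return site_point(edge.anchor.species_name, edge.anchor.site_index)
        return layout.positions[edge.species]

    def edge_endpoints(edge: Edge) -> tuple[tuple[float, float], tuple[float, float]]:
        sp_pt = species_endpoint(edge)
        rx_pt = layout.positions[edge.rule]
        return (sp_pt, rx_pt) if edge.role is EdgeRole.REACTANT else (rx_pt, sp_pt)

    # canvas extent
    xs, ys = [], []
    for n in nodes:
        (x, y), (w, h) = layout.positions[n], layout.sizes[n]
        xs += [x - w / 2, x + w / 2]
        ys += [y - h / 2, y + h / 2]
    margin = 40.0
    panel_w = 320.0 if selection and selection.transform_pair else 0.0
    min_x = (min(xs) if xs else 0.0) - margin
    min_y = (min(ys) if ys else 0.0) - margin
    width = (max(xs) if xs else 0.0) + margin + panel_w - min_x
    height = (max(ys) if ys else 0.0) + margin - min_y

    root = ET.Element("svg", {
        "xmlns": SVG_NS,
        "version": "1.1",
        "viewBox": f"{_fmt(min_x)} {_fmt(min_y)} {_fmt(width)} {_fmt(height)}",
        "width": _fmt(width),
        "height": _fmt(height),
    })

    highlighted_edges = selection.highlighted_edges if selection else frozenset()

    # ---- edges ----
    edges_g = ET.SubElement(root, "g", {"id": "edges"})
    for j, edge in enumerate(graph.edges):
        p0, p1 = edge_endpoints(edge)
        chord = (p1[0] - p0[0], p1[1] - p0[1])
        length = (chord[0] ** 2 + chord[1] ** 2) ** 0.5
        if length < 1e-9:
            perp = (0.0, 0.0)
        else:
            perp = (-chord[1] / length, chord[0] / length)
        sign = 1.0 if edge.occurrence_index % 2 == 0 else -1.0
        bow = 0.15 * length * sign * (1 + edge.occurrence_index // 2)
        c1 = (p0[0] + chord[0] / 3 + perp[0] * bow,
              p0[1] + chord[1] / 3 + perp[1] * bow)
        c2 = (p0[0] + 2 * chord[0] / 3 + perp[0] * bow,
              p0[1] + 2 * chord[1] / 3 + perp[1] * bow)

        highlighted = edge.id in highlighted_edges
        override = layout.visual_overrides.get(f"edge:{edge.id}", {})
        width_px = float(override.get("width", style.edge_width))
        if highlighted:
            width_px *= style.highlight_width_mult
        opacity = style.highlight_opacity if highlighted else style.base_opacity

        g = ET.SubElement(edges_g, "g", {
            "id": f"e{j}-{_slug(edge.id)}",
            "fill": "none",
            "stroke-width": _fmt(width_px),
            "opacity": _fmt(opacity),
        })
        title = ET.SubElement(g, "title")
        title.text = (f"{edge.rule} [{edge.category.value}] "
                      f"rate = {edge.rate_constant:g}")
        n_seg = 8
        for k in range(n_seg):
            t0, t1 = k / n_seg, (k + 1) / n_seg
            q0, k0, k1, q1 = _bezier_split(p0, c1, c2, p1, t0, t1)
            ET.SubElement(g, "path", {
                "d": (f"M {_fmt(q0[0])} {_fmt(q0[1])} "
                      f"C {_fmt(k0[0])} {_fmt(k0[1])}, "
                      f"{_fmt(k1[0])} {_fmt(k1[1])}, "
                      f"{_fmt(q1[0])} {_fmt(q1[1])}"),
                "stroke": edge_color(edge.category, (t0 + t1) / 2, style),
            })

    # ---- reaction nodes (small arrows) ----
    rx_g = ET.SubElement(root, "g", {"id": "reactions"})
    for n in reaction_order:
        x, y = layout.positions[n]
        incident = graph.edges_of_rule(n)
        r_pts = [species_endpoint(e) for e in incident
                 if e.role is EdgeRole.REACTANT]
        p_pts = [species_endpoint(e) for e in incident
                 if e.role is EdgeRole.PRODUCT]

        def centroid(pts):
            return (sum(p[0] for p in pts) / len(pts),
                    sum(p[1] for p in pts) / len(pts)) if pts else (x, y)

        rc, pc = centroid(r_pts), centroid(p_pts)
        dx, dy = pc[0] - rc[0], pc[1] - rc[1]
        norm = (dx ** 2 + dy ** 2) ** 0.5
        ux, uy = (dx / norm, dy / norm) if norm > 1e-9 else (1.0, 0.0)
        s = m.reaction_size / 2
        tip = (x + ux * s, y + uy * s)
        left = (x - ux * s - uy * s * 0.7, y - uy * s + ux * s * 0.7)
        right = (x - ux * s + uy * s * 0.7, y - uy * s - ux * s * 0.7)
        color = style.category_hue[
            RuleCategory(graph.to_networkx().nodes[n]["category"])]
        g = ET.SubElement(rx_g, "g", {"id": rx_id[n]})
        title = ET.SubElement(g, "title")
        title.text = n
        ET.SubElement(g, "polygon", {
            "points": " ".join(f"{_fmt(px)},{_fmt(py)}"
                               for px, py in (tip, left, right)),
            "fill": color,
            "stroke": "#333333",
            "stroke-width": "0.8",
        })

    # ---- species glyphs ----
    sp_g = ET.SubElement(root, "g", {"id": "species"})
    overlays = selection.overlays if selection else {}
    searched = selection.searched_species if selection else None
    for n in species_order:
        sp_overlays = overlays.get(n, ())
        _emit_species_glyph(
            sp_g, model, n, layout.positions[n], plans[n], style,
            elem_id=sp_id[n],
            overlay=sp_overlays[0] if sp_overlays else None,
            sublabel=", ".join(o.complex_name for o in sp_overlays) or None,
            searched=(n == searched),
        )

    # ---- detached transformation panel ----
    if selection and selection.transform_pair:
        panel = ET.SubElement(root, "g", {"id": "transform-panel"})
        px = (max(xs) if xs else 0.0) + margin + panel_w / 2
        py = (min(ys) if ys else 0.0) + 120.0
        before, after = selection.transform_pair
        before_plan = glyph_plan(model, before[0], m)
        for k, ((sp_name, cx_name), label) in enumerate(
                ((before, "before"), (after, "after"))):
            cx_obj = model.complex(sp_name, cx_name)
            plan = glyph_plan(model, sp_name, m)
            _emit_species_glyph(
                panel, model, sp_name, (px, py + k * (plan.height + 60.0)),
                plan, style,
                elem_id=f"transform-{label}",
                overlay=Overlay(sp_name, cx_name, label),
                sublabel=cx_name,
                complex_states=cx_obj,
            )
        ET.SubElement(panel, "path", {
            "d": (f"M {_fmt(px)} {_fmt(py + before_plan.height / 2 + 8)} l 0 30"),
            "stroke": "#333333",
            "stroke-width": "2",
        })

    return ET.tostring(root, encoding="unicode") + "\n"


def _emit_species_glyph(parent, model: Model, species_name: str,
                        pos: tuple[float, float], plan, style: StylePalette,
                        elem_id: str,
                        overlay: Optional[Overlay] = None,
                        sublabel: Optional[str] = None,
                        searched: bool = False,
                        complex_states: Optional[Complex] = None) -> None:
    m = style.metrics
    x, y = pos
    g = ET.SubElement(parent, "g", {
        "id": elem_id,
        "transform": f"translate({_fmt(x)} {_fmt(y)})",
    })
    if searched:
        ET.SubElement(g, "rect", {
            "x": _fmt(-plan.width / 2 - 4), "y": _fmt(-plan.height / 2 - 4),
            "width": _fmt(plan.width + 8), "height": _fmt(plan.height + 8),
            "fill": "none", "stroke": "#cc0000", "stroke-width": "2",
        })
    for e in plan.ellipses:
        ET.SubElement(g, "ellipse", {
            "cx": _fmt(e.cx), "cy": _fmt(e.cy),
            "rx": _fmt(e.rx), "ry": _fmt(e.ry),
            "fill": "#f7f7f2", "stroke": "#444444", "stroke-width": "1.2",
        })

    states = None
    if complex_states is not None:
        states = complex_states.state_map
    elif overlay is not None:
        states = model.complex(species_name, overlay.complex_name).state_map

    for sq in plan.squares:
        sx, sy, side = sq.x - m.square_side / 2, sq.y - m.square_side / 2, \
            m.square_side
        value = states.get(sq.key) if states else None
        fill = {TriState.ON: "#222222", TriState.OFF: "#ffffff"}.get(
            value, "#ffffff")
        ET.SubElement(g, "rect", {
            "x": _fmt(sx), "y": _fmt(sy), "width": _fmt(side),
            "height": _fmt(side), "fill": fill, "stroke": "#222222",
            "stroke-width": "0.9",
            "class": f"state-{value.value if value else 'unset'}",
        })
        if value is TriState.DONT_CARE:
            # don't-care glyph: half-filled square
            ET.SubElement(g, "rect", {
                "x": _fmt(sx), "y": _fmt(sy), "width": _fmt(side / 2),
                "height": _fmt(side), "fill": "#222222", "stroke": "none",
                "class": "state-dont_care-half",
            })

    # bond lines last, then site circles on top
    extra_bound = set(overlay.bond_site_indices) if overlay else set()
    for a, b in plan.bonds:
        pa, pb = plan.site_positions[a], plan.site_positions[b]
        ET.SubElement(g, "line", {
            "x1": _fmt(pa[0]), "y1": _fmt(pa[1]),
            "x2": _fmt(pb[0]), "y2": _fmt(pb[1]),
            "stroke": style.bond_color, "stroke-width": "1.6",
            "class": "bond",
        })
    for idx in sorted(plan.site_positions):
        sx, sy = plan.site_positions[idx]
        bound = idx in plan.bound_sites or idx in extra_bound
        ET.SubElement(g, "circle", {
            "cx": _fmt(sx), "cy": _fmt(sy), "r": _fmt(m.site_radius),
            "fill": style.bond_color if bound else "#ffffff",
            "stroke": "#222222", "stroke-width": "1",
            "class": "site",
        })
        label = ET.SubElement(g, "text", {
            "x": _fmt(sx), "y": _fmt(sy + 2.3),
            "text-anchor": "middle", "font-size": "6.5",
            "fill": "#ffffff" if bound else "#222222",
            "font-family": "sans-serif",
        })
        label.text = str(idx)

    name_el = ET.SubElement(g, "text", {
        "x": "0", "y": _fmt(plan.label_y),
        "text-anchor": "middle", "font-size": "11",
        "font-family": "sans-serif", "fill": "#111111",
    })
    name_el.text = species_name
    if sublabel:
        sub = ET.SubElement(g, "text", {
            "x": "0", "y": _fmt(plan.label_y + m.label_height),
            "text-anchor": "middle", "font-size": "10",
            "font-family": "sans-serif", "fill": "#1a3fbf",
            "class": "complex-sublabel",
        })
        sub.text = sublabel


# ---------------------------------------------------------------------------
# DOT / GraphML export


def _dot_escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace('"', '\\"')


def export_dot(graph: NetworkGraph) -> str:
    """Graphviz DOT export carrying kind/category/role/anchor attributes."""
    lines = ["digraph network {"]
    for sp in sorted(graph.species_nodes):
        lines.append(f'  "{_dot_escape(sp)}" [kind="species"];')
    for rx in sorted(graph.reaction_nodes):
        cat = graph.to_networkx().nodes[rx]["category"]
        lines.append(f'  "{_dot_escape(rx)}" [kind="reaction", category="{cat}"];')
    for e in graph.edges:
        anchor_site = e.anchor.site_index if e.anchor is not None else 0
        lines.append(
            f'  "{_dot_escape(e.source)}" -> "{_dot_escape(e.target)}" '
            f'[role="{e.role.value}", category="{e.category.value}", '
            f'anchor_site={anchor_site}, occurrence={e.occurrence_index}, '
            f'edge_id="{_dot_escape(e.id)}"];'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"


def export_graphml(graph: NetworkGraph) -> str:
    """GraphML export; reparses (e.g. via networkx) to an isomorphic graph."""
    g = nx.MultiDiGraph()
    for sp in sorted(graph.species_nodes):
        g.add_node(sp, kind="species", category="")
    for rx in sorted(graph.reaction_nodes):
        g.add_node(rx, kind="reaction",
                   category=graph.to_networkx().nodes[rx]["category"])
    for e in graph.edges:
        g.add_edge(
            e.source, e.target, key=e.id,
            role=e.role.value,
            category=e.category.value,
            anchor_species=e.anchor.species_name if e.anchor else "",
            anchor_site=e.anchor.site_index if e.anchor else 0,
            occurrence=e.occurrence_index,
            rate_constant=float(e.rate_constant),
        )
    return "\n".join(nx.generate_graphml(g)) + "\n"
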
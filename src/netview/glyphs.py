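"""Glyph geometry for species nodes.

A species glyph is drawn from the iconography of visual rule-based modelling:
one ellipse per molecule component (molecule instances side by side, their
components stacked), a circle per binding site on the owning component's
ellipse boundary (index printed inside, filled when structurally bound, blue
line between bonded pairs) and a square per state variable (filled = on,
open = off, half-filled = don't care). Both the layout engine (node sizes)
and the SVG renderer consume the same plan, so boxes used for overlap
removal match what is drawn.

All plan coordinates are local, centred on the glyph origin; y grows
downward (canvas convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .model import Model, StateKey


@dataclass(frozen=True)
class GlyphMetrics:
    ellipse_rx: float = 30.0
    ellipse_ry: float = 17.0
    col_gap: float = 12.0
    row_gap: float = 10.0
    site_radius: float = 6.0
    square_side: float = 8.0
    square_gap: float = 3.0
    label_height: float = 14.0
    reaction_size: float = 16.0


@dataclass(frozen=True)
class EllipseSpec:
    cx: float
    cy: float
    rx: float
    ry: float
    instance_id: str
    component_name: str


@dataclass(frozen=True)
class SquareSpec:
    x: float  # centre
    y: float
    key: StateKey


@dataclass
class GlyphPlan:
    width: float
    height: float
    ellipses: list[EllipseSpec] = field(default_factory=list)
    site_positions: dict[int, tuple[float, float]] = field(default_factory=dict)
    bound_sites: set[int] = field(default_factory=set)
    bonds: list[tuple[int, int]] = field(default_factory=list)
    squares: list[SquareSpec] = field(default_factory=list)
    label_y: float = 0.0


def glyph_plan(model: Model, species_name: str,
               metrics: GlyphMetrics | None = None) -> GlyphPlan:
    """Compute the drawing plan (and bounding box) for one species glyph."""
    m = metrics or GlyphMetrics()
    sp = model.species_by_name(species_name)
    instances = sp.molecule_instances

    col_w = 2 * m.ellipse_rx + m.col_gap
    row_h = 2 * m.ellipse_ry + m.row_gap

    n_cols = max(1, len(instances))
    rows_per_col = [
        max(1, len(model.molecule(mol).components)) for _, mol in instances
    ] or [1]
    n_rows = max(rows_per_col)

    body_w = n_cols * col_w - m.col_gap
    body_h = n_rows * row_h - m.row_gap
    pad = m.site_radius + 2
    width = body_w + 2 * pad
    height = body_h + 2 * pad + m.label_height

    plan = GlyphPlan(width=width, height=height)
    plan.label_y = body_h / 2 + pad + m.label_height * 0.75

    # site indices follow species-wide declaration order
    site_idx = 0
    for ci, (inst, mol_name) in enumerate(instances):
        mol = model.molecule(mol_name)
        cx0 = -body_w / 2 + m.ellipse_rx + ci * col_w
        for ri, comp in enumerate(mol.components):
            cy0 = -body_h / 2 + m.ellipse_ry + ri * row_h
            plan.ellipses.append(
                EllipseSpec(cx0, cy0, m.ellipse_rx, m.ellipse_ry, inst, comp.name)
            )
            n_sites = len(comp.binding_sites)
            for k in range(n_sites):
                site_idx += 1
                # spread sites along the ellipse boundary, starting at the
                # bottom (y-down canvas) and stepping counterclockwise
                angle = math.pi / 2 + 2 * math.pi * k / max(n_sites, 1)
                plan.site_positions[site_idx] = (
                    cx0 + m.ellipse_rx * math.cos(angle),
                    cy0 + m.ellipse_ry * math.sin(angle),
                )
            n_vars = len(comp.state_variables)
            for k, var in enumerate(comp.state_variables):
                sx = cx0 + (k - (n_vars - 1) / 2) * (m.square_side + m.square_gap)
                plan.squares.append(SquareSpec(sx, cy0 - m.square_side * 0.2,
                                               (inst, comp.name, var)))

    for a, b in sp.structural_bonds:
        plan.bonds.append((a, b))
        plan.bound_sites.add(a)
        plan.bound_sites.add(b)
    return plan


def node_size(model: Model, graph_node: str, kind: str,
              metrics: GlyphMetrics | None = None) -> tuple[float, float]:
    """Bounding-box size for a graph node (species glyph or reaction arrow)."""
    m = metrics or GlyphMetrics()
    if kind == "reaction":
        return (m.reaction_size, m.reaction_size)
    plan = glyph_plan(model, graph_node, m)
    return (plan.width, plan.height)
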
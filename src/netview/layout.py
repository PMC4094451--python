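"""Node layout: force-directed, level-based and circular modes.

* FORCE — spring-embedder positions (seed-deterministic) followed by
  iterative pairwise box-separation so no two node boxes overlap.
* LEVEL — nodes arranged into horizontal bands by *reaction distance* to a
  reference species (the minimal number of reactions connecting them);
  reaction nodes sit on half-levels between their adjacent species bands;
  within a band, order follows a barycenter heuristic over the previous
  bands with name tie-breaks. y grows downward; the reference sits on top.
* CIRCULAR — polar conversion of the level layout: radius = level x ring
  spacing (reference at the centre), angle derived from the level-layout
  abscissa, with within-ring angular order preserved.

Layouts are pure functions of (graph, mode, reference, seed, params).
:func:`save_layout` / :func:`load_layout` persist positions, sizes and
free-form visual attribute overrides (e.g. edge widths) in a JSON auxiliary
file so a visualization can be regenerated identically; loading against a
graph whose node set changed reports a reconciliation diff and positions the
new nodes with a fallback force pass while leaving known positions intact.
"""

from __future__ import annotations

import json
import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import networkx as nx

from .glyphs import GlyphMetrics, node_size
from .graph import NetworkGraph
from .model import NetviewError, NotFoundError

logger = logging.getLogger(__name__)

LAYOUT_FORMAT_VERSION = "1.0"


class LayoutParseError(NetviewError):
    """Malformed auxiliary layout file."""


class LayoutMode(Enum):
    FORCE = "force"
    LEVEL = "level"
    CIRCULAR = "circular"


@dataclass(frozen=True)
class LayoutParams:
    """Tunables in abstract canvas units (pixel-like)."""

    level_spacing: float = 110.0  # minimum vertical band distance (LEVEL)
    x_gap: float = 28.0  # horizontal gap between boxes in a band
    ring_spacing: float = 170.0  # minimum ring distance (CIRCULAR)
    gutter: float = 120.0  # abscissa gutter left open in the polar map
    node_gap: float = 6.0  # minimum clearance between node boxes
    overlap_tolerance: float = 1e-6
    max_overlap_iterations: int = 500
    metrics: GlyphMetrics = field(default_factory=GlyphMetrics)


@dataclass
class LayoutDiff:
    """Reconciliation report from loading a layout against a changed graph."""

    missing_nodes: tuple[str, ...] = ()  # in the graph, absent from the file
    stale_nodes: tuple[str, ...] = ()  # in the file, absent from the graph

    def __bool__(self) -> bool:
        return bool(self.missing_nodes or self.stale_nodes)


@dataclass
class Layout:
    positions: dict[str, tuple[float, float]]
    sizes: dict[str, tuple[float, float]]
    mode: LayoutMode
    reference: Optional[str] = None
    visual_overrides: dict[str, dict] = field(default_factory=dict)
    reconciliation: LayoutDiff = field(default_factory=LayoutDiff)


@dataclass
class LevelAssignment:
    """Reaction-distance levels relative to a reference species node."""

    levels: dict[str, int]  # species -> whole-number reaction distance
    reaction_levels: dict[str, float]  # reaction node -> half-level
    unreachable: set[str]


# ---------------------------------------------------------------------------
# levels


def reaction_distance(graph: NetworkGraph, reference: str) -> LevelAssignment:
    """Breadth-first reaction distances over the undirected bipartite graph.

    A species' level is half its bipartite shortest-path length from the
    reference (always an integer); a reaction node sits at the minimal
    adjacent species level + 0.5. Unreachable nodes are collected separately.
    """
    if reference not in graph.species_nodes:
        raise NotFoundError(f"reference {reference!r} is not a species node")
    und = graph.to_networkx().to_undirected(as_view=True)
    dist = nx.single_source_shortest_path_length(und, reference)
    levels = {n: d // 2 for n, d in dist.items() if n in graph.species_nodes}
    reaction_levels = {}
    for n, d in dist.items():
        if n in graph.reaction_nodes:
            adjacent = [levels[s] for s in und.neighbors(n) if s in levels]
            reaction_levels[n] = min(adjacent) + 0.5
    unreachable = (graph.species_nodes | graph.reaction_nodes) - set(dist)
    return LevelAssignment(levels, reaction_levels, unreachable)


# ---------------------------------------------------------------------------
# shared helpers


def _node_sizes(graph: NetworkGraph,
                params: LayoutParams) -> dict[str, tuple[float, float]]:
    sizes = {}
    for n in sorted(graph.species_nodes):
        sizes[n] = node_size(graph.model, n, "species", params.metrics)
    for n in sorted(graph.reaction_nodes):
        sizes[n] = node_size(graph.model, n, "reaction", params.metrics)
    return sizes


def boxes_overlap(pa, sa, pb, sb, tolerance: float = 1e-6) -> bool:
    """Axis-aligned box intersection test (boxes centred on positions)."""
    return (abs(pa[0] - pb[0]) < (sa[0] + sb[0]) / 2 - tolerance
            and abs(pa[1] - pb[1]) < (sa[1] + sb[1]) / 2 - tolerance)


def overlapping_pairs(layout: Layout, tolerance: float = 1e-6):
    names = sorted(layout.positions)
    out = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if boxes_overlap(layout.positions[a], layout.sizes[a],
                             layout.positions[b], layout.sizes[b], tolerance):
                out.append((a, b))
    return out


def _remove_overlaps(positions: dict[str, tuple[float, float]],
                     sizes: dict[str, tuple[float, float]],
                     params: LayoutParams,
                     axis: Optional[str] = None) -> None:
    """Iterative pairwise box separation along the connecting vector.

    Runs until no box pair intersects (with ``node_gap`` clearance) or the
    iteration cap is reached; ``axis='x'`` restricts movement to the x axis
    (used by the banded layouts to preserve level monotonicity).
    """
    names = sorted(positions)
    gap = params.node_gap
    for _ in range(params.max_overlap_iterations):
        moved = False
        for i, a in enumerate(names):
            for j in range(i + 1, len(names)):
                b = names[j]
                ax, ay = positions[a]
                bx, by = positions[b]
                need_x = (sizes[a][0] + sizes[b][0]) / 2 + gap - abs(ax - bx)
                need_y = (sizes[a][1] + sizes[b][1]) / 2 + gap - abs(ay - by)
                if need_x <= params.overlap_tolerance or \
                        need_y <= params.overlap_tolerance:
                    continue
                dx, dy = bx - ax, by - ay
                if axis == "x":
                    dy = 0.0
                norm = math.hypot(dx, dy)
                if norm < 1e-9:
                    # coincident centres: deterministic separation direction
                    angle = 2 * math.pi * ((i * 31 + j) % 360) / 360.0
                    dx, dy = math.cos(angle), math.sin(angle)
                    if axis == "x":
                        dx, dy = 1.0, 0.0
                    norm = 1.0
                ux, uy = dx / norm, dy / norm
                sx = need_x / abs(ux) if abs(ux) > 1e-9 else math.inf
                sy = need_y / abs(uy) if abs(uy) > 1e-9 else math.inf
                step = min(sx, sy) + 1e-3
                positions[a] = (ax - ux * step / 2, ay - uy * step / 2)
                positions[b] = (bx + ux * step / 2, by + uy * step / 2)
                moved = True
        if not moved:
            return


# ---------------------------------------------------------------------------
# force layout


def layout_force(graph: NetworkGraph, seed: int = 0,
                 params: LayoutParams | None = None) -> Layout:
    """Spring-embedder layout followed by overlap removal; seed-deterministic."""
    params = params or LayoutParams()
    sizes = _node_sizes(graph, params)
    nodes = sorted(sizes)
    if not nodes:
        return Layout({}, {}, LayoutMode.FORCE)
    if len(nodes) == 1:
        return Layout({nodes[0]: (0.0, 0.0)}, sizes, LayoutMode.FORCE)

    und = nx.Graph()
    und.add_nodes_from(nodes)
    und.add_edges_from((e.source, e.target) for e in graph.edges)
    raw = nx.spring_layout(und, seed=seed)
    mean_diag = sum(math.hypot(*sizes[n]) for n in nodes) / len(nodes)
    scale = math.sqrt(len(nodes)) * (mean_diag + params.node_gap) * 0.75
    positions = {n: (float(raw[n][0]) * scale, float(raw[n][1]) * scale)
                 for n in nodes}
    _remove_overlaps(positions, sizes, params)
    return Layout(positions, sizes, LayoutMode.FORCE)


# ---------------------------------------------------------------------------
# level layout


def _banded_positions(graph: NetworkGraph, assignment: LevelAssignment,
                      sizes: dict[str, tuple[float, float]],
                      params: LayoutParams):
    """Group nodes into (level -> ordered node list) with barycenter ordering."""
    level_of: dict[str, float] = {}
    for n, lv in assignment.levels.items():
        level_of[n] = float(lv)
    for n, lv in assignment.reaction_levels.items():
        level_of[n] = lv

    bands: dict[float, list[str]] = defaultdict(list)
    for n, lv in level_of.items():
        bands[lv].append(n)

    und = graph.to_networkx().to_undirected(as_view=True)
    x_order: dict[str, float] = {}
    ordered_bands: dict[float, list[str]] = {}
    for lv in sorted(bands):
        members = bands[lv]

        def key(n: str):
            placed = [x_order[m] for m in und.neighbors(n)
                      if m in x_order and level_of.get(m, lv) < lv]
            bary = sum(placed) / len(placed) if placed else math.inf
            return (bary, n)

        members = sorted(members, key=key)
        ordered_bands[lv] = members
        for i, n in enumerate(members):
            x_order[n] = float(i)
    return level_of, ordered_bands


def _assign_band_x(members, sizes, params) -> dict[str, float]:
    total = sum(sizes[n][0] for n in members) + \
        params.x_gap * max(0, len(members) - 1)
    xs = {}
    cursor = -total / 2
    for n in members:
        xs[n] = cursor + sizes[n][0] / 2
        cursor += sizes[n][0] + params.x_gap
    return xs


def layout_level(graph: NetworkGraph, reference: str,
                 params: LayoutParams | None = None) -> Layout:
    """Level-based layout: y = level x level_spacing, reference on top."""
    params = params or LayoutParams()
    sizes = _node_sizes(graph, params)
    assignment = reaction_distance(graph, reference)
    level_of, bands = _banded_positions(graph, assignment, sizes, params)

    max_h = max((h for _, h in sizes.values()), default=0.0)
    spacing = max(params.level_spacing, 2 * (max_h + params.node_gap))

    positions: dict[str, tuple[float, float]] = {}
    for lv, members in bands.items():
        xs = _assign_band_x(members, sizes, params)
        for n in members:
            positions[n] = (xs[n], lv * spacing)

    # unreachable nodes go to a trailing band below everything else
    if assignment.unreachable:
        trailing = (max(level_of.values(), default=0.0) + 2.0) * spacing
        members = sorted(assignment.unreachable)
        xs = _assign_band_x(members, sizes, params)
        for n in members:
            positions[n] = (xs[n], trailing)

    # band spacing and in-band slotting already separate the boxes; the
    # x-constrained pass mops up any residue without breaking monotonicity
    _remove_overlaps(positions, sizes, params, axis="x")
    return Layout(positions, sizes, LayoutMode.LEVEL, reference=reference)


# ---------------------------------------------------------------------------
# circular layout


def layout_circular(graph: NetworkGraph, reference: str,
                    params: LayoutParams | None = None) -> Layout:
    """Polar conversion of the level layout; reference fixed at the centre."""
    params = params or LayoutParams()
    base = layout_level(graph, reference, params)
    sizes = base.sizes
    assignment = reaction_distance(graph, reference)

    level_of: dict[str, float] = {n: float(lv)
                                  for n, lv in assignment.levels.items()}
    level_of.update(assignment.reaction_levels)
    if assignment.unreachable:
        outer = max(level_of.values(), default=0.0) + 2.0
        for n in assignment.unreachable:
            level_of[n] = outer

    diag = {n: math.hypot(*sizes[n]) for n in sizes}
    max_diag = max(diag.values(), default=0.0)

    rings: dict[float, list[str]] = defaultdict(list)
    for n, lv in level_of.items():
        if lv > 0:
            rings[lv].append(n)

    # ring spacing: respect the configured minimum, keep consecutive
    # half-level rings clear of each other, and give every ring enough
    # circumference for its members (60% angular fill)
    spacing = max(params.ring_spacing, 2 * (max_diag + params.node_gap))
    for lv, members in rings.items():
        needed_circ = sum(diag[n] + params.node_gap for n in members)
        spacing = max(spacing, needed_circ / (2 * math.pi * 0.6) / lv)

    xs = {n: base.positions[n][0] for n in base.positions}
    x_min = min(xs.values(), default=0.0)
    x_max = max(xs.values(), default=0.0)
    span = x_max - x_min

    positions: dict[str, tuple[float, float]] = {reference: (0.0, 0.0)}
    for lv in sorted(rings):
        members = sorted(rings[lv], key=lambda n: xs[n])
        r = lv * spacing
        theta = {
            n: 2 * math.pi * (xs[n] - x_min) / (span + params.gutter)
            if span + params.gutter > 0 else 0.0
            for n in members
        }
        # order-preserving minimum angular gaps within the ring
        for i in range(1, len(members)):
            a, b = members[i - 1], members[i]
            min_gap = ((diag[a] + diag[b]) / 2 + params.node_gap) / r
            if theta[b] < theta[a] + min_gap:
                theta[b] = theta[a] + min_gap
        if members:
            wrap_gap = ((diag[members[0]] + diag[members[-1]]) / 2
                        + params.node_gap) / r
            if theta[members[-1]] - theta[members[0]] > 2 * math.pi - wrap_gap:
                # crowded ring: redistribute cumulatively (fits by sizing)
                cursor = 0.0
                for i, n in enumerate(members):
                    if i:
                        prev = members[i - 1]
                        cursor += ((diag[prev] + diag[n]) / 2
                                   + params.node_gap) / r
                    theta[n] = cursor
        for n in members:
            positions[n] = (r * math.cos(theta[n]), r * math.sin(theta[n]))

    return Layout(positions, sizes, LayoutMode.CIRCULAR, reference=reference)


# ---------------------------------------------------------------------------
# persistence


def save_layout(layout: Layout, graph: NetworkGraph) -> str:
    """Serialize a layout (positions, sizes, visual overrides) to JSON text."""
    missing = (graph.species_nodes | graph.reaction_nodes) - set(layout.positions)
    if missing:
        raise NetviewError(
            "layout does not cover the graph; missing: " + ", ".join(sorted(missing))
        )
    doc = {
        "format_version": LAYOUT_FORMAT_VERSION,
        "mode": layout.mode.value,
        "reference": layout.reference,
        "positions": {n: [p[0], p[1]] for n, p in layout.positions.items()},
        "sizes": {n: [s[0], s[1]] for n, s in layout.sizes.items()},
        "visual_overrides": layout.visual_overrides,
    }
    return json.dumps(doc, indent=2, sort_keys=True) + "\n"


def load_layout(text: str, graph: NetworkGraph, seed: int = 0,
                params: LayoutParams | None = None) -> Layout:
    """Load an auxiliary layout file and reconcile it with the graph.

    Known node positions are restored bit-exactly. Nodes present in the
    graph but absent from the file are placed by a fallback force pass with
    all known nodes held fixed; file entries for nodes no longer in the
    graph are dropped. Both groups are reported in ``layout.reconciliation``
    and logged as warnings — a node-set mismatch is not fatal.
    """
    params = params or LayoutParams()
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as je:
        raise LayoutParseError(
            f"malformed layout file: {je.msg} (line {je.lineno})"
        ) from None
    if not isinstance(doc, dict) or "positions" not in doc:
        raise LayoutParseError("layout file must be an object with 'positions'")
    try:
        mode = LayoutMode(doc.get("mode", "force"))
    except ValueError:
        raise LayoutParseError(f"unknown layout mode {doc.get('mode')!r}") from None

    graph_nodes = graph.species_nodes | graph.reaction_nodes
    file_positions = doc["positions"]
    if not isinstance(file_positions, dict):
        raise LayoutParseError("'positions' must be an object")

    stale = tuple(sorted(set(file_positions) - graph_nodes))
    missing = tuple(sorted(graph_nodes - set(file_positions)))
    diff = LayoutDiff(missing_nodes=missing, stale_nodes=stale)
    if diff:
        logger.warning(
            "layout/graph node sets differ: %d new node(s) %s, %d stale entr(ies) %s",
            len(missing), list(missing), len(stale), list(stale),
        )

    positions = {
        n: (float(p[0]), float(p[1]))
        for n, p in file_positions.items()
        if n in graph_nodes
    }
    sizes = {
        n: (float(s[0]), float(s[1]))
        for n, s in (doc.get("sizes") or {}).items()
        if n in graph_nodes
    }
    for n in graph_nodes - set(sizes):
        sizes[n] = node_size(graph.model, n, graph.node_kind(n), params.metrics)

    if missing:
        und = nx.Graph()
        und.add_nodes_from(sorted(graph_nodes))
        und.add_edges_from((e.source, e.target) for e in graph.edges)
        fixed = [n for n in sorted(positions)]
        if fixed:
            seeded = dict(positions)
            for n in missing:
                seeded[n] = (0.0, 0.0)
            raw = nx.spring_layout(und, pos=seeded, fixed=fixed, seed=seed)
        else:
            raw = nx.spring_layout(und, seed=seed)
        for n in missing:
            positions[n] = (float(raw[n][0]), float(raw[n][1]))

    return Layout(
        positions=positions,
        sizes=sizes,
        mode=mode,
        reference=doc.get("reference"),
        visual_overrides=dict(doc.get("visual_overrides") or {}),
        reconciliation=diff,
    )
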
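"""Independent oracles used by the test suite.

Everything here is deliberately naive (linear scans, truth tables, BFS via
networkx on a rebuilt simple graph, O(n^2) box intersection) and never calls
the code paths it is used to check.
"""

from __future__ import annotations

import re
from collections import Counter

import networkx as nx

from netview import Model, TriState

# --- brute-force query oracles ---------------------------------------------


def contains_molecule_oracle(model: Model, species_name: str,
                             molecule_name: str) -> bool:
    for sp in model.species:
        if sp.name == species_name:
            return any(mol == molecule_name for _, mol in sp.molecule_instances)
    return False


def reactions_of_complex_oracle(model: Model, ref: tuple[str, str]) -> set[str]:
    hits = set()
    for rule in model.rules:
        if ref in tuple(rule.reactants) + tuple(rule.products):
            hits.add(rule.name)
    return hits


def name_filter_oracle(model: Model, term: str):
    """(species MATCH set, species CHILD_MATCH set, complex MATCH set)."""
    t = term.lower()
    sp_match, sp_child, cx_match = set(), set(), set()
    for sp in model.species:
        kids = {c.name for c in sp.complexes if t in c.name.lower()}
        cx_match |= {(sp.name, k) for k in kids}
        if t in sp.name.lower():
            sp_match.add(sp.name)
        elif kids:
            sp_child.add(sp.name)
    return sp_match, sp_child, cx_match


#: exhaustive truth table of the symmetric tri-state matching relation
TRI_MATCH_TABLE = {
    (p, c): (p is TriState.DONT_CARE or c is TriState.DONT_CARE or p is c)
    for p in TriState for c in TriState
}


def match_oracle(pattern_map, state_map) -> bool:
    return all(TRI_MATCH_TABLE[(want, state_map[key])]
               for key, want in pattern_map.items())


# --- graph oracles ----------------------------------------------------------


def edge_count_oracle(model: Model) -> int:
    return sum(len(r.reactants) + len(r.products) for r in model.rules)


def bfs_levels_oracle(graph, reference) -> dict[str, float]:
    """All-pairs-free BFS on an independently rebuilt undirected graph."""
    g = nx.Graph()
    g.add_nodes_from(graph.species_nodes | graph.reaction_nodes)
    for e in graph.edges:
        g.add_edge(e.source, e.target)
    dist = nx.single_source_shortest_path_length(g, reference)
    return {n: d / 2 for n, d in dist.items()}


def boxes_intersect_oracle(positions, sizes, tol=1e-6):
    names = sorted(positions)
    bad = []
    for i, a in enumerate(names):
        ax, ay = positions[a]
        aw, ah = sizes[a]
        for b in names[i + 1:]:
            bx, by = positions[b]
            bw, bh = sizes[b]
            if (abs(ax - bx) < (aw + bw) / 2 - tol
                    and abs(ay - by) < (ah + bh) / 2 - tol):
                bad.append((a, b))
    return bad


# --- export readers (tests only) --------------------------------------------

_DOT_NODE = re.compile(r'^\s*"((?:[^"\\]|\\.)*)"\s*\[(.*)\];$')
_DOT_EDGE = re.compile(r'^\s*"((?:[^"\\]|\\.)*)"\s*->\s*"((?:[^"\\]|\\.)*)"\s*\[(.*)\];$')


def _unescape(text: str) -> str:
    return text.replace('\\"', '"').replace("\\\\", "\\")


def _parse_attrs(blob: str) -> dict:
    attrs = {}
    for part in re.findall(r'(\w+)=("(?:[^"\\]|\\.)*"|\S+?)(?:,|$)', blob):
        key, val = part
        if val.startswith('"'):
            val = _unescape(val[1:-1])
        attrs[key] = val
    return attrs


def parse_dot(text: str):
    """Minimal DOT reader for the exporter's own output."""
    nodes, edges = {}, []
    for line in text.splitlines():
        m = _DOT_EDGE.match(line)
        if m:
            edges.append((_unescape(m.group(1)), _unescape(m.group(2)),
                          _parse_attrs(m.group(3))))
            continue
        m = _DOT_NODE.match(line)
        if m:
            nodes[_unescape(m.group(1))] = _parse_attrs(m.group(2))
    return nodes, edges


def graph_fingerprint(graph) -> tuple:
    """Structure multiset used for round-trip isomorphism checks."""
    nodes = tuple(sorted(
        (n, "species") for n in graph.species_nodes
    ) + sorted((n, "reaction") for n in graph.reaction_nodes))
    edges = tuple(sorted(Counter(
        (e.source, e.target, e.role.value,
         e.anchor.site_index if e.anchor else 0, e.occurrence_index)
        for e in graph.edges
    ).items()))
    return nodes, edges
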
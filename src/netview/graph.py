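"""Directed bipartite species-reaction network graphs.

The network graph has one node per complex species and one *intermediate*
node per reaction rule. A reactant occurrence contributes an edge from the
species node to the reaction node, a product occurrence one from the
reaction node to the species node — so the node count is exactly
``n_species + n_rules`` and the edge count ``3(A + D) + 2T`` for A
associations, D dissociations and T transformations.

Association and dissociation edges are anchored at the binding sites they
involve (the species-side endpoint of the rendered curve points at that
site's circle); transformation edges, which involve no binding sites, anchor
at the species-node center, represented here as ``anchor=None``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

import networkx as nx

from .model import (
    BindingSiteRef,
    InvalidModelError,
    Model,
    NotFoundError,
    ReactionRule,
    RuleCategory,
    validate_model,
)

#: Anchor value for edges pointing at a species-node center.
CENTER = None


class EdgeRole(Enum):
    REACTANT = "reactant"
    PRODUCT = "product"


@dataclass(frozen=True)
class Edge:
    """One reactant/product occurrence of a species in a rule.

    ``occurrence_index`` distinguishes parallel edges produced by homotypic
    rules (the same species occurring twice on one side). ``anchor`` is the
    involved binding site, or ``None`` (CENTER) when the edge points at the
    species-node center.
    """

    id: str
    rule: str
    species: str
    role: EdgeRole
    category: RuleCategory
    source: str
    target: str
    anchor: Optional[BindingSiteRef]
    occurrence_index: int
    rate_constant: float


@dataclass(frozen=True)
class GraphStats:
    n_species_nodes: int
    n_reaction_nodes: int
    n_nodes: int
    n_edges: int
    per_category: dict[str, int] = field(default_factory=dict, hash=False)

    def to_dict(self) -> dict:
        return {
            "n_species_nodes": self.n_species_nodes,
            "n_reaction_nodes": self.n_reaction_nodes,
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "per_category": dict(self.per_category),
        }


class NetworkGraph:
    """Bipartite species-reaction multigraph with site-anchored edges.

    Wraps a :class:`networkx.MultiDiGraph` (accessible via
    :meth:`to_networkx`) whose node ids are the plain species and rule names,
    tagged with a ``kind`` attribute.
    """

    def __init__(self, model: Model):
        self.model = model
        self.species_nodes: set[str] = {sp.name for sp in model.species}
        self.reaction_nodes: set[str] = {r.name for r in model.rules}
        self.edges: list[Edge] = []
        self._g = nx.MultiDiGraph()
        for sp in model.species:
            self._g.add_node(
                sp.name,
                kind="species",
                n_sites=model.site_count(sp.name),
                n_components=sum(
                    len(model.molecule(mol).components)
                    for _, mol in sp.molecule_instances
                ),
            )
        for rule in model.rules:
            self._g.add_node(rule.name, kind="reaction",
                             category=rule.category.value)

    def _add_edge(self, edge: Edge) -> None:
        self.edges.append(edge)
        self._g.add_edge(edge.source, edge.target, key=edge.id, edge=edge)

    def to_networkx(self) -> nx.MultiDiGraph:
        return self._g

    @property
    def n_nodes(self) -> int:
        return len(self.species_nodes) + len(self.reaction_nodes)

    def node_kind(self, node: str) -> str:
        if node in self.species_nodes:
            return "species"
        if node in self.reaction_nodes:
            return "reaction"
        raise NotFoundError(f"no node named {node!r}")

    def edges_of(self, node: str) -> list[Edge]:
        """All edges incident to a node, in insertion order."""
        self.node_kind(node)
        return [e for e in self.edges if e.source == node or e.target == node]

    def edges_of_rule(self, rule_name: str) -> list[Edge]:
        if rule_name not in self.reaction_nodes:
            raise NotFoundError(f"no reaction node named {rule_name!r}")
        return [e for e in self.edges if e.rule == rule_name]

    def neighbors(self, node: str) -> set[str]:
        self.node_kind(node)
        return set(self._g.predecessors(node)) | set(self._g.successors(node))

    def edge_by_id(self, edge_id: str) -> Edge:
        for e in self.edges:
            if e.id == edge_id:
                return e
        raise NotFoundError(f"no edge with id {edge_id!r}")


def _new_bond_anchor(model: Model, rule: ReactionRule) -> Optional[BindingSiteRef]:
    """Anchor site for an association's product edge: the newly formed bond.

    The new bond is identified structurally as the unique structural bond of
    the product species whose removal splits the species' instance graph
    into two connected components whose molecule-name multisets equal the
    two reactants'. Returns the lower-indexed site of that bond, or CENTER
    when no unique such bond exists.
    """
    product_sp = model.species_by_name(rule.products[0][0])
    if not product_sp.structural_bonds:
        return CENTER
    table = model.site_table(product_sp.name)
    site_instance = {info.index: info.instance_id for info in table}
    reactant_multisets = sorted(
        Counter(mol for _, mol in model.species_by_name(sp).molecule_instances)
        for sp, _ in rule.reactants
    )
    instance_mol = dict(product_sp.molecule_instances)

    candidates = []
    for bond in product_sp.structural_bonds:
        g = nx.Graph()
        g.add_nodes_from(inst for inst, _ in product_sp.molecule_instances)
        for other in product_sp.structural_bonds:
            if other == bond:
                continue
            g.add_edge(site_instance[other[0]], site_instance[other[1]])
        comps = list(nx.connected_components(g))
        if len(comps) != 2:
            continue
        multisets = sorted(Counter(instance_mol[i] for i in comp)
                           for comp in comps)
        if multisets == reactant_multisets:
            candidates.append(bond)
    if len(candidates) != 1:
        return CENTER
    return BindingSiteRef(product_sp.name, min(candidates[0]))


def build_network_graph(model: Model) -> NetworkGraph:
    """Build the bipartite species-reaction graph from a validated model.

    Refuses invalid models with the aggregated validation report. Building
    twice from the same model yields identical graphs including edge order.
    """
    violations = [v for v in validate_model(model) if v.severity == "error"]
    if violations:
        raise InvalidModelError(violations)
    collisions = {sp.name for sp in model.species} & {r.name for r in model.rules}
    if collisions:
        # species and rules share the graph's node-id namespace
        raise NotFoundError(
            "species and rule names must be distinct to build a graph; "
            "rename: " + ", ".join(sorted(collisions))
        )

    graph = NetworkGraph(model)
    for rule in model.rules:
        occ: Counter = Counter()
        sides = (
            (EdgeRole.REACTANT, rule.reactants),
            (EdgeRole.PRODUCT, rule.products),
        )
        for role, refs in sides:
            for sp_name, _cx in refs:
                k = occ[(role, sp_name)]
                occ[(role, sp_name)] += 1
                anchor = _edge_anchor(model, rule, role, sp_name, k)
                source, target = (
                    (sp_name, rule.name) if role is EdgeRole.REACTANT
                    else (rule.name, sp_name)
                )
                graph._add_edge(Edge(
                    id=f"{rule.name}::{role.value}::{sp_name}::{k}",
                    rule=rule.name,
                    species=sp_name,
                    role=role,
                    category=rule.category,
                    source=source,
                    target=target,
                    anchor=anchor,
                    occurrence_index=k,
                    rate_constant=rule.rate_constant,
                ))
    return graph


def _edge_anchor(model: Model, rule: ReactionRule, role: EdgeRole,
                 sp_name: str, occurrence: int) -> Optional[BindingSiteRef]:
    if rule.category is RuleCategory.TRANSFORMATION:
        return CENTER
    if rule.category is RuleCategory.ASSOCIATION:
        if role is EdgeRole.REACTANT:
            if rule.bond_sites is None:
                return CENTER
            matching = [ref for ref in rule.bond_sites
                        if ref.species_name == sp_name]
            return matching[occurrence] if occurrence < len(matching) else CENTER
        return _new_bond_anchor(model, rule)
    # dissociation: the dissolved bond lives in the reactant species
    if role is EdgeRole.REACTANT and rule.bond_sites is not None:
        matching = [ref for ref in rule.bond_sites if ref.species_name == sp_name]
        if matching:
            return BindingSiteRef(sp_name, min(r.site_index for r in matching))
    return CENTER


def graph_stats(graph: NetworkGraph) -> GraphStats:
    """Node/edge counts and the per-category rule tally."""
    per_category = Counter(
        graph.to_networkx().nodes[r]["category"] for r in graph.reaction_nodes
    )
    for cat in RuleCategory:
        per_category.setdefault(cat.value, 0)
    return GraphStats(
        n_species_nodes=len(graph.species_nodes),
        n_reaction_nodes=len(graph.reaction_nodes),
        n_nodes=graph.n_nodes,
        n_edges=len(graph.edges),
        per_category=dict(per_category),
    )


def reactions_of_complex(model: Model, graph: NetworkGraph,
                         complex_ref: tuple[str, str]) -> set[str]:
    """Rule names whose reactants or products list the given (species, complex)."""
    sp_name, cx_name = complex_ref
    model.complex(sp_name, cx_name)  # raises NotFoundError if absent
    return {
        rule.name
        for rule in model.rules
        if complex_ref in rule.reactants or complex_ref in rule.products
    }


def edges_at_site(graph: NetworkGraph, site: BindingSiteRef) -> list[Edge]:
    """All edges anchored exactly at the given binding site, in stable order."""
    if site.species_name not in graph.species_nodes:
        raise NotFoundError(f"no species node named {site.species_name!r}")
    n_sites = graph.to_networkx().nodes[site.species_name]["n_sites"]
    if not (1 <= site.site_index <= n_sites):
        raise NotFoundError(
            f"species {site.species_name!r} has no site {site.site_index} "
            f"(1..{n_sites})"
        )
    return [e for e in graph.edges if e.anchor == site]
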
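"""Filtering, tri-state pattern search and selection semantics.

These operations drive highlighting and detail rendering: name/molecule
filters colour the species/complex tree, state-pattern searches find the
complexes of one species matching a tri-state constraint set and light up
every reaction they participate in, and reaction/complex selections produce
the overlay data (rule-side complexes with their states and bond statuses)
that the renderer embeds into the network view.

Tri-state matching is symmetric: a constraint matches a stored value when
either side is don't-care or both agree. Stored rule-side complexes are
patterns themselves, so don't-care on the stored side matches any query.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .graph import NetworkGraph, reactions_of_complex
from .model import (
    Complex,
    Model,
    NotFoundError,
    RuleCategory,
    StateKey,
    TriState,
    species_contains_molecule,
)


class HighlightState(Enum):
    MATCH = "match"  # rendered yellow
    CHILD_MATCH = "child_match"  # species only; rendered light blue
    NONE = "none"


@dataclass
class HighlightReport:
    """Per-entity highlight states from a filter operation."""

    species: dict[str, HighlightState] = field(default_factory=dict)
    complexes: dict[tuple[str, str], HighlightState] = field(default_factory=dict)

    def matching_species(self) -> set[str]:
        return {n for n, h in self.species.items() if h is HighlightState.MATCH}

    def matching_complexes(self) -> set[tuple[str, str]]:
        return {k for k, h in self.complexes.items() if h is HighlightState.MATCH}


@dataclass(frozen=True)
class StatePattern:
    """Tri-state constraint set over one species' state variables.

    Unconstrained variables default to don't-care, mirroring the clickable
    state squares of the interactive search.
    """

    species_name: str
    constraints: tuple[tuple[StateKey, TriState], ...] = ()

    @classmethod
    def of(cls, species_name: str,
           constraints: dict[StateKey, TriState]) -> "StatePattern":
        return cls(species_name, tuple(sorted(constraints.items())))

    def constraint_map(self) -> dict[StateKey, TriState]:
        return dict(self.constraints)


@dataclass(frozen=True)
class Overlay:
    """A complex to display on a species node during a reaction selection."""

    species: str
    complex_name: str
    role: str  # 'reactant' | 'product'
    bond_site_indices: tuple[int, ...] = ()


@dataclass
class SelectionResult:
    highlighted_rules: frozenset[str] = frozenset()
    highlighted_edges: frozenset[str] = frozenset()
    overlays: dict[str, tuple[Overlay, ...]] = field(default_factory=dict)
    searched_species: Optional[str] = None  # rendered with a red border
    matched_complexes: tuple[str, ...] = ()
    transform_pair: Optional[tuple[tuple[str, str], tuple[str, str]]] = None

    def to_dict(self) -> dict:
        return {
            "highlighted_rules": sorted(self.highlighted_rules),
            "highlighted_edges": sorted(self.highlighted_edges),
            "overlays": {
                sp: [
                    {
                        "complex": o.complex_name,
                        "role": o.role,
                        "bond_sites": list(o.bond_site_indices),
                    }
                    for o in ovs
                ]
                for sp, ovs in self.overlays.items()
            },
            "searched_species": self.searched_species,
            "matched_complexes": list(self.matched_complexes),
            "transform_pair": (
                [list(self.transform_pair[0]), list(self.transform_pair[1])]
                if self.transform_pair else None
            ),
        }


# ---------------------------------------------------------------------------
# filters


def filter_by_name(model: Model, term: str) -> HighlightReport:
    """Case-insensitive substring filter on species and complex names.

    A species is MATCH when its own name contains the term, CHILD_MATCH when
    it does not but a child complex does (the collapsed-list hint), NONE
    otherwise; complexes are MATCH/NONE.
    """
    if not term:
        raise ValueError("filter term must be non-empty")
    needle = term.lower()
    report = HighlightReport()
    for sp in model.species:
        child_hit = False
        for cx in sp.complexes:
            hit = needle in cx.name.lower()
            child_hit = child_hit or hit
            report.complexes[(sp.name, cx.name)] = (
                HighlightState.MATCH if hit else HighlightState.NONE
            )
        if needle in sp.name.lower():
            report.species[sp.name] = HighlightState.MATCH
        elif child_hit:
            report.species[sp.name] = HighlightState.CHILD_MATCH
        else:
            report.species[sp.name] = HighlightState.NONE
    return report


def filter_by_molecule(model: Model, molecule_name: str) -> HighlightReport:
    """Highlight species (and, hereditarily, all their complexes) containing
    the molecule. A complex contains a molecule iff its species does, so
    CHILD_MATCH never occurs here; unknown molecules yield all NONE."""
    report = HighlightReport()
    for sp in model.species:
        state = (HighlightState.MATCH
                 if species_contains_molecule(sp, molecule_name)
                 else HighlightState.NONE)
        report.species[sp.name] = state
        for cx in sp.complexes:
            report.complexes[(sp.name, cx.name)] = state
    return report


# ---------------------------------------------------------------------------
# tri-state search


def match_state_pattern(pattern: StatePattern, complex_: Complex) -> bool:
    """Symmetric tri-state match of a pattern against a stored complex.

    Per variable: don't-care on either side matches, otherwise the values
    must agree. Raises ValueError on a species mismatch or a constraint on
    a variable the complex does not carry.
    """
    if pattern.species_name != complex_.species_name:
        raise ValueError(
            f"pattern is for species {pattern.species_name!r}, complex belongs "
            f"to {complex_.species_name!r}"
        )
    for key, want in pattern.constraints:
        if key not in complex_.state_map:
            raise ValueError(f"unknown state variable {key!r} for species "
                             f"{pattern.species_name!r}")
        have = complex_.state_map[key]
        if want is TriState.DONT_CARE or have is TriState.DONT_CARE:
            continue
        if want is not have:
            return False
    return True


def search_species(model: Model, graph: NetworkGraph,
                   pattern: StatePattern) -> SelectionResult:
    """Find the pattern's matching complexes and every reaction they touch.

    Highlights all rules having a matching complex as reactant or product,
    plus every edge incident to those rules; the searched species is flagged
    for red-border rendering.
    """
    sp = model.species_by_name(pattern.species_name)
    declared = set(model.state_keys(sp.name))
    for key, _ in pattern.constraints:
        if key not in declared:
            raise NotFoundError(
                f"species {sp.name!r} declares no state variable {key!r}"
            )
    matches = [cx.name for cx in sp.complexes
               if match_state_pattern(pattern, cx)]
    match_refs = {(sp.name, name) for name in matches}
    rules = {
        rule.name
        for rule in model.rules
        if match_refs & (set(rule.reactants) | set(rule.products))
    }
    edges = frozenset(e.id for e in graph.edges if e.rule in rules)
    return SelectionResult(
        highlighted_rules=frozenset(rules),
        highlighted_edges=edges,
        searched_species=sp.name,
        matched_complexes=tuple(matches),
    )


# ---------------------------------------------------------------------------
# selections


def select_reaction(model: Model, graph: NetworkGraph,
                    rule_name: str) -> SelectionResult:
    """Selection data for one rule: highlighted edges plus display overlays.

    Associations/dissociations overlay each involved species node with its
    rule-side complex (including the bond status at the rule's bond sites);
    transformations instead carry a detached before/after complex pair for
    side-panel rendering.
    """
    rule = model.rule(rule_name)
    edges = frozenset(e.id for e in graph.edges_of_rule(rule_name))
    if rule.category is RuleCategory.TRANSFORMATION:
        return SelectionResult(
            highlighted_rules=frozenset({rule_name}),
            highlighted_edges=edges,
            transform_pair=(rule.reactants[0], rule.products[0]),
        )

    bond_sites_by_species: dict[str, list[int]] = {}
    for ref in rule.bond_sites or ():
        bond_sites_by_species.setdefault(ref.species_name, []).append(
            ref.site_index)

    overlays: dict[str, list[Overlay]] = {}
    for role, refs in (("reactant", rule.reactants), ("product", rule.products)):
        for sp_name, cx_name in refs:
            overlays.setdefault(sp_name, []).append(Overlay(
                species=sp_name,
                complex_name=cx_name,
                role=role,
                bond_site_indices=tuple(bond_sites_by_species.get(sp_name, ())),
            ))
    return SelectionResult(
        highlighted_rules=frozenset({rule_name}),
        highlighted_edges=edges,
        overlays={sp: tuple(ovs) for sp, ovs in overlays.items()},
    )


def select_complex(model: Model, graph: NetworkGraph,
                   complex_ref: tuple[str, str]) -> SelectionResult:
    """Highlight every reaction (and its edges) the complex participates in."""
    rules = reactions_of_complex(model, graph, complex_ref)
    edges = frozenset(e.id for e in graph.edges if e.rule in rules)
    return SelectionResult(
        highlighted_rules=frozenset(rules),
        highlighted_edges=edges,
    )


def reactions_by_category(model: Model) -> dict[RuleCategory, list]:
    """Partition all rules by category, stable in model order."""
    groups: dict[RuleCategory, list] = {cat: [] for cat in RuleCategory}
    for rule in model.rules:
        groups[rule.category].append(rule)
    return groups
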
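"""Bipartite graph construction, counts, anchors and lookups."""

import networkx as nx
import pytest

from netview import (
    BindingSiteRef,
    Complex,
    ComplexSpecies,
    Component,
    EdgeRole,
    InvalidModelError,
    Model,
    Molecule,
    NotFoundError,
    ReactionRule,
    RuleCategory,
    build_network_graph,
    edges_at_site,
    graph_stats,
    reactions_of_complex,
)
from helpers import (
    edge_count_oracle,
    reactions_of_complex_oracle,
)


def minimal_association_model():
    """Three species, one association rule: A + B -> AB."""
    mols = tuple(Molecule(n, (Component("c", binding_sites=("s",)),))
                 for n in ("A", "B"))
    species = (
        ComplexSpecies("A", (("a", "A"),), complexes=(Complex("a0", "A"),)),
        ComplexSpecies("B", (("b", "B"),), complexes=(Complex("b0", "B"),)),
        ComplexSpecies("AB", (("a", "A"), ("b", "B")),
                       structural_bonds=((1, 2),),
                       complexes=(Complex("ab0", "AB"),)),
    )
    rule = ReactionRule("bind", RuleCategory.ASSOCIATION,
                        reactants=(("A", "a0"), ("B", "b0")),
                        products=(("AB", "ab0"),),
                        bond_sites=(BindingSiteRef("A", 1),
                                    BindingSiteRef("B", 1)))
    return Model(molecules=mols, species=species, rules=(rule,))


def homotypic_model():
    """Dimerization: two occurrences of the same reactant species."""
    mol = Molecule("M", (Component("c", binding_sites=("s1", "s2")),))
    species = (
        ComplexSpecies("Mono", (("m", "M"),), complexes=(Complex("m0", "Mono"),)),
        ComplexSpecies("Dimer", (("m1", "M"), ("m2", "M")),
                       structural_bonds=((1, 3),),
                       complexes=(Complex("d0", "Dimer"),)),
    )
    rule = ReactionRule("dimerize", RuleCategory.ASSOCIATION,
                        reactants=(("Mono", "m0"), ("Mono", "m0")),
                        products=(("Dimer", "d0"),),
                        bond_sites=(BindingSiteRef("Mono", 1),
                                    BindingSiteRef("Mono", 2)))
    return Model(molecules=(mol,), species=species, rules=(rule,))


# ---------------------------------------------------------------------------
# counts


def test_egfr_graph_has_17_nodes_and_18_edges(egfr_graph):
    stats = graph_stats(egfr_graph)
    assert stats.n_nodes == 17
    assert stats.n_edges == 18
    assert stats.per_category == {"association": 6, "dissociation": 0,
                                  "transformation": 0}


def test_gprotein_graph_has_19_nodes_and_29_edges(gprot_graph):
    stats = graph_stats(gprot_graph)
    assert stats.n_nodes == 19
    assert stats.n_edges == 29


def test_single_association_gives_4_nodes_3_edges():
    graph = build_network_graph(minimal_association_model())
    stats = graph_stats(graph)
    assert stats.n_nodes == 4
    assert stats.n_edges == 3
    roles = sorted(e.role.value for e in graph.edges)
    assert roles == ["product", "reactant", "reactant"]


def test_empty_model_gives_empty_stats():
    stats = graph_stats(build_network_graph(Model()))
    assert stats.n_nodes == stats.n_edges == 0


@pytest.mark.parametrize("seed", range(8))
def test_node_and_edge_count_formulas(make_random, seed):
    model = make_random(seed, n_species=6, n_rules=12)
    graph = build_network_graph(model)
    stats = graph_stats(graph)
    assert stats.n_nodes == len(model.species) + len(model.rules)
    assert stats.n_edges == edge_count_oracle(model)
    a = stats.per_category["association"]
    d = stats.per_category["dissociation"]
    t = stats.per_category["transformation"]
    assert stats.n_edges == 3 * (a + d) + 2 * t


# ---------------------------------------------------------------------------
# structure


@pytest.mark.parametrize("seed", range(8))
def test_graph_is_bipartite_by_two_coloring(make_random, seed):
    graph = build_network_graph(make_random(seed))
    for e in graph.edges:
        if e.role is EdgeRole.REACTANT:
            assert e.source in graph.species_nodes
            assert e.target in graph.reaction_nodes
        else:
            assert e.source in graph.reaction_nodes
            assert e.target in graph.species_nodes
    und = nx.Graph()
    und.add_nodes_from(graph.species_nodes | graph.reaction_nodes)
    und.add_edges_from((e.source, e.target) for e in graph.edges)
    color = nx.algorithms.bipartite.color(und) if und.number_of_edges() else {}
    for e in graph.edges:
        assert color[e.source] != color[e.target]


def test_reaction_node_degrees_match_category(gprot_graph):
    g = gprot_graph.to_networkx()
    for rx in gprot_graph.reaction_nodes:
        cat = g.nodes[rx]["category"]
        expected = {"association": (2, 1), "dissociation": (1, 2),
                    "transformation": (1, 1)}[cat]
        assert (g.in_degree(rx), g.out_degree(rx)) == expected


def test_building_twice_yields_identical_graphs(gprot):
    g1 = build_network_graph(gprot)
    g2 = build_network_graph(gprot)
    assert g1.edges == g2.edges
    assert g1.species_nodes == g2.species_nodes


def test_homotypic_rule_produces_distinguished_parallel_edges():
    graph = build_network_graph(homotypic_model())
    reactant_edges = [e for e in graph.edges if e.role is EdgeRole.REACTANT]
    assert len(reactant_edges) == 2
    assert [e.occurrence_index for e in reactant_edges] == [0, 1]
    # each occurrence picks up its own bond site, in rule order
    assert [e.anchor.site_index for e in reactant_edges] == [1, 2]
    assert graph_stats(graph).n_edges == 3


def test_invalid_model_is_refused():
    model = minimal_association_model()
    model.rules = (ReactionRule("bad", RuleCategory.ASSOCIATION,
                                reactants=(("A", "a0"),),
                                products=(("AB", "ab0"),)),)
    with pytest.raises(InvalidModelError):
        build_network_graph(model)


# ---------------------------------------------------------------------------
# anchors


def test_transformation_edges_anchor_at_species_centers(gprot_graph):
    t_edges = [e for e in gprot_graph.edges
               if e.category is RuleCategory.TRANSFORMATION]
    assert len(t_edges) == 8
    assert all(e.anchor is None for e in t_edges)


def test_association_reactant_edges_anchor_at_bond_sites(egfr_graph):
    for e in egfr_graph.edges:
        if e.role is EdgeRole.REACTANT:
            assert e.anchor is not None
            assert e.anchor.species_name == e.species


def test_association_product_edge_anchors_at_new_bond_lower_site(egfr_graph):
    edge = next(e for e in egfr_graph.edges
                if e.rule == "Grb2 binds pY1068" and e.role is EdgeRole.PRODUCT)
    assert edge.anchor == BindingSiteRef("EGFR_Grb2_pY1068", 2)


def test_recruitment_product_anchor_identifies_the_new_bond(gprot_graph):
    """The new receptor-Galpha bond is found among three structural bonds."""
    edge = next(e for e in gprot_graph.edges
                if e.rule == "G protein recruitment"
                and e.role is EdgeRole.PRODUCT)
    assert edge.anchor == BindingSiteRef("LigRec_Gabg", 3)


def test_dissociation_reactant_edge_anchors_at_dissolved_bond(gprot_graph):
    edge = next(e for e in gprot_graph.edges
                if e.rule == "ligand dissociation"
                and e.role is EdgeRole.REACTANT)
    assert edge.anchor == BindingSiteRef("Ligated Receptor", 1)


def test_edges_at_site_returns_exact_anchor_matches(egfr_graph):
    reactant = edges_at_site(egfr_graph, BindingSiteRef("EGFR", 2))
    product = edges_at_site(egfr_graph, BindingSiteRef("EGFR_Grb2_pY1068", 2))
    ids = {e.id for e in reactant} | {e.id for e in product}
    assert ids == {
        "Grb2 binds pY1068::reactant::EGFR::0",
        "Grb2 binds pY1068::product::EGFR_Grb2_pY1068::0",
    }


def test_unused_membrane_anchor_site_has_no_edges(egfr_graph):
    assert edges_at_site(egfr_graph, BindingSiteRef("EGFR", 5)) == []


def test_edges_at_unknown_site_is_a_lookup_error(egfr_graph):
    with pytest.raises(NotFoundError):
        edges_at_site(egfr_graph, BindingSiteRef("EGFR", 9))
    with pytest.raises(NotFoundError):
        edges_at_site(egfr_graph, BindingSiteRef("NoSpecies", 1))


# ---------------------------------------------------------------------------
# reactions_of_complex


def test_rec_inactive_participates_in_exactly_two_reactions(gprot, gprot_graph):
    rules = reactions_of_complex(gprot, gprot_graph, ("Receptor", "Rec inactive"))
    assert rules == {"receptor ligation", "ligand dissociation"}


def test_unknown_complex_is_a_lookup_error(gprot, gprot_graph):
    with pytest.raises(NotFoundError):
        reactions_of_complex(gprot, gprot_graph, ("Receptor", "ghost"))


def test_unreferenced_complex_has_no_reactions(make_random):
    model = make_random(3, n_species=4, n_rules=0)
    graph = build_network_graph(model)
    sp = model.species[0]
    assert reactions_of_complex(model, graph,
                                (sp.name, sp.complexes[0].name)) == set()


@pytest.mark.parametrize("seed", range(6))
def test_reactions_of_complex_matches_rule_scan_oracle(make_random, seed):
    model = make_random(seed)
    graph = build_network_graph(model)
    for sp in model.species:
        for cx in sp.complexes:
            ref = (sp.name, cx.name)
            assert reactions_of_complex(model, graph, ref) == \
                reactions_of_complex_oracle(model, ref)
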
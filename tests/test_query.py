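"""Filters, tri-state search and selection semantics."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netview import (
    Complex,
    ComplexSpecies,
    Component,
    HighlightState,
    Model,
    Molecule,
    NotFoundError,
    RuleCategory,
    StatePattern,
    TriState,
    build_network_graph,
    filter_by_molecule,
    filter_by_name,
    match_state_pattern,
    reactions_by_category,
    search_species,
    select_complex,
    select_reaction,
)
from helpers import match_oracle, name_filter_oracle

ON, OFF, DC = TriState.ON, TriState.OFF, TriState.DONT_CARE


# ---------------------------------------------------------------------------
# name filter


def test_gdp_term_matches_complex_and_blues_its_species(gprot):
    report = filter_by_name(gprot, "gdp")
    assert report.complexes[("LigRec_Gabg", "LigRec_Gab_GDP")] \
        is HighlightState.MATCH
    assert report.species["LigRec_Gabg"] is HighlightState.CHILD_MATCH


def test_name_filter_is_case_insensitive(gprot):
    for term in ("gdp", "GDP", "gDp"):
        report = filter_by_name(gprot, term)
        assert report.matching_complexes() == \
            filter_by_name(gprot, "gdp").matching_complexes()
        assert report.species == filter_by_name(gprot, "gdp").species


def test_unmatched_term_highlights_nothing(gprot):
    report = filter_by_name(gprot, "zzz-no-such-name")
    assert all(h is HighlightState.NONE for h in report.species.values())
    assert all(h is HighlightState.NONE for h in report.complexes.values())


def test_empty_term_is_an_argument_error(gprot):
    with pytest.raises(ValueError):
        filter_by_name(gprot, "")


@pytest.mark.parametrize("seed", range(6))
def test_name_filter_equals_substring_scan_oracle(make_random, seed):
    model = make_random(seed)
    rng = random.Random(seed)
    for term in ("s", "S1", "c0", "_C1", rng.choice("abcSC_0123")):
        report = filter_by_name(model, term)
        sp_match, sp_child, cx_match = name_filter_oracle(model, term)
        assert report.matching_species() == sp_match
        assert {n for n, h in report.species.items()
                if h is HighlightState.CHILD_MATCH} == sp_child
        assert report.matching_complexes() == cx_match


# ---------------------------------------------------------------------------
# molecule filter


def test_ligand_filter_highlights_exactly_three_species(gprot):
    report = filter_by_molecule(gprot, "Ligand")
    assert report.matching_species() == \
        {"Ligand", "Ligated Receptor", "LigRec_Gabg"}


def test_absent_molecule_highlights_nothing(gprot):
    report = filter_by_molecule(gprot, "Kinase")
    assert report.matching_species() == set()
    assert report.matching_complexes() == set()


@pytest.mark.parametrize("fixture_name", ["egfr", "gprot"])
def test_molecule_filter_is_hereditary(fixture_name, request):
    """Species and all their complexes always share the highlight state."""
    model = request.getfixturevalue(fixture_name)
    for mol in [m.name for m in model.molecules]:
        report = filter_by_molecule(model, mol)
        assert not any(h is HighlightState.CHILD_MATCH
                       for h in report.species.values())
        for (sp, _cx), h in report.complexes.items():
            assert h is report.species[sp]


# ---------------------------------------------------------------------------
# tri-state matching


def _single_var_model(stored: TriState):
    mol = Molecule("M", (Component("c", state_variables=("v",),
                                   binding_sites=("s",)),))
    sp = ComplexSpecies("S", (("m", "M"),), complexes=(
        Complex("cx", "S", {("m", "c", "v"): stored}),))
    return Model(molecules=(mol,), species=(sp,))


@pytest.mark.parametrize("stored", list(TriState))
@pytest.mark.parametrize("queried", list(TriState))
def test_tristate_matching_truth_table(stored, queried):
    """Don't-care on either side matches; concrete values must agree."""
    model = _single_var_model(stored)
    pattern = StatePattern.of("S", {("m", "c", "v"): queried})
    expected = (stored is DC or queried is DC or stored is queried)
    assert match_state_pattern(pattern, model.complex("S", "cx")) == expected


def test_all_dont_care_pattern_matches_every_complex(gprot):
    for sp in gprot.species:
        pattern = StatePattern.of(sp.name, {})
        for cx in sp.complexes:
            assert match_state_pattern(pattern, cx)


def test_species_mismatch_is_an_argument_error(gprot):
    pattern = StatePattern.of("Receptor", {})
    with pytest.raises(ValueError):
        match_state_pattern(pattern, gprot.complex("Ligand", "Ligand"))


@settings(deadline=None, derandomize=True, max_examples=60)
@given(st.lists(st.tuples(st.sampled_from(list(TriState)),
                          st.sampled_from(list(TriState))),
                min_size=1, max_size=6))
def test_multivariable_matching_equals_per_variable_oracle(pairs):
    mol = Molecule("M", (Component("c",
                                   state_variables=tuple(
                                       f"v{i}" for i in range(len(pairs))),
                                   binding_sites=("s",)),))
    stored = {("m", "c", f"v{i}"): s for i, (s, _q) in enumerate(pairs)}
    queried = {("m", "c", f"v{i}"): q for i, (_s, q) in enumerate(pairs)}
    sp = ComplexSpecies("S", (("m", "M"),),
                        complexes=(Complex("cx", "S", stored),))
    model = Model(molecules=(mol,), species=(sp,))
    pattern = StatePattern.of("S", queried)
    assert match_state_pattern(pattern, model.complex("S", "cx")) == \
        match_oracle(queried, stored)


@pytest.mark.parametrize("seed", range(5))
def test_relaxing_a_pattern_only_grows_the_match_set(make_random, seed):
    model = make_random(seed, n_species=6, n_rules=0, max_state_vars=3)
    rng = random.Random(seed)
    for sp in model.species:
        keys = list(model.state_keys(sp.name))
        if not keys:
            continue
        tight_map = {k: rng.choice((ON, OFF)) for k in keys}
        relaxed_map = dict(tight_map)
        relaxed_map[rng.choice(keys)] = DC
        tight = StatePattern.of(sp.name, tight_map)
        relaxed = StatePattern.of(sp.name, relaxed_map)
        tight_matches = {c.name for c in sp.complexes
                         if match_state_pattern(tight, c)}
        relaxed_matches = {c.name for c in sp.complexes
                           if match_state_pattern(relaxed, c)}
        assert tight_matches <= relaxed_matches


# ---------------------------------------------------------------------------
# state search


def test_receptor_off_search_finds_three_complexes_three_reactions(
        gprot, gprot_graph):
    pattern = StatePattern.of(
        "Receptor", {("rec", "intracellular", "active"): OFF})
    result = search_species(gprot, gprot_graph, pattern)
    assert set(result.matched_complexes) == \
        {"Rec inactive", "Receptor_2", "Rec inactive unbound"}
    assert result.highlighted_rules == \
        {"receptor ligation", "ligand dissociation", "receptor recycling"}
    assert result.searched_species == "Receptor"
    for edge_id in result.highlighted_edges:
        assert gprot_graph.edge_by_id(edge_id).rule in result.highlighted_rules


def test_bound_plcg992_blocks_all_plcg_binding(egfr, egfr_graph):
    pattern = StatePattern.of(
        "EGFR", {("egfr", "cytoplasmic", "bndPLCg992"): ON})
    result = search_species(egfr, egfr_graph, pattern)
    plcg_rules = {r.name for r in egfr.rules
                  if any(sp == "PLCg1" for sp, _ in r.reactants)}
    assert result.highlighted_rules & plcg_rules == set()


def test_bound_shc1148_blocks_plcg_at_1173_and_shc_at_1148(egfr, egfr_graph):
    pattern = StatePattern.of(
        "EGFR", {("egfr", "cytoplasmic", "bndSHC1148"): ON})
    result = search_species(egfr, egfr_graph, pattern)
    assert "PLCg1 binds pY1173" not in result.highlighted_rules
    assert "Shc binds pY1148" not in result.highlighted_rules


def test_search_on_species_without_complexes_is_empty():
    mol = Molecule("M", (Component("c", binding_sites=("s",)),))
    sp = ComplexSpecies("Bare", (("m", "M"),))
    model = Model(molecules=(mol,), species=(sp,))
    graph = build_network_graph(model)
    result = search_species(model, graph, StatePattern.of("Bare", {}))
    assert result.matched_complexes == ()
    assert result.highlighted_rules == frozenset()


def test_search_unknown_species_or_variable_is_a_lookup_error(
        gprot, gprot_graph):
    with pytest.raises(NotFoundError):
        search_species(gprot, gprot_graph, StatePattern.of("Nope", {}))
    with pytest.raises(NotFoundError):
        search_species(gprot, gprot_graph, StatePattern.of(
            "Receptor", {("rec", "intracellular", "ghost"): ON}))


# ---------------------------------------------------------------------------
# selections


def test_selecting_receptor_ligation_overlays_the_three_complexes(
        gprot, gprot_graph):
    result = select_reaction(gprot, gprot_graph, "receptor ligation")
    assert set(result.overlays) == {"Ligand", "Receptor", "Ligated Receptor"}
    assert result.overlays["Receptor"][0].complex_name == "Rec inactive"
    assert result.overlays["Ligated Receptor"][0].role == "product"
    # bond status at the rule's bond sites is carried for rendering
    assert result.overlays["Receptor"][0].bond_site_indices == (1,)


def test_selecting_gdp_gtp_exchange_yields_before_after_pair(
        gprot, gprot_graph):
    result = select_reaction(gprot, gprot_graph,
                             "Receptor mediated Galpha GDP GTP exchange")
    assert result.transform_pair == (("LigRec_Gabg", "LigRec_Gab_GDP"),
                                     ("LigRec_Gabg", "LigRec_Gabg_GTP"))
    assert result.overlays == {}


@pytest.mark.parametrize("fixture_name", ["egfr", "gprot"])
def test_selected_rule_highlights_exactly_its_incident_edges(
        fixture_name, request):
    model = request.getfixturevalue(fixture_name)
    graph = build_network_graph(model)
    for rule in model.rules:
        result = select_reaction(model, graph, rule.name)
        assert result.highlighted_rules == {rule.name}
        assert result.highlighted_edges == \
            {e.id for e in graph.edges_of_rule(rule.name)}


def test_selecting_rec_inactive_highlights_two_reactions(gprot, gprot_graph):
    result = select_complex(gprot, gprot_graph, ("Receptor", "Rec inactive"))
    assert result.highlighted_rules == {"receptor ligation",
                                        "ligand dissociation"}


def test_selecting_unknown_entities_raises(gprot, gprot_graph):
    with pytest.raises(NotFoundError):
        select_reaction(gprot, gprot_graph, "ghost rule")
    with pytest.raises(NotFoundError):
        select_complex(gprot, gprot_graph, ("Receptor", "ghost"))


# ---------------------------------------------------------------------------
# reaction list


def test_egfr_rules_group_entirely_under_association(egfr):
    groups = reactions_by_category(egfr)
    assert len(groups[RuleCategory.ASSOCIATION]) == 6
    assert groups[RuleCategory.DISSOCIATION] == []
    assert groups[RuleCategory.TRANSFORMATION] == []


def test_category_groups_partition_the_rules_in_model_order(gprot):
    groups = reactions_by_category(gprot)
    names = [r.name for group in groups.values() for r in group]
    assert sorted(names) == sorted(r.name for r in gprot.rules)
    for cat, group in groups.items():
        model_order = [r.name for r in gprot.rules if r.category is cat]
        assert [r.name for r in group] == model_order


def test_empty_model_yields_three_empty_groups():
    groups = reactions_by_category(Model())
    assert all(group == [] for group in groups.values())
    assert set(groups) == set(RuleCategory)
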
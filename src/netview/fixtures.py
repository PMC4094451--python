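"""Packaged example models and a seeded random-model generator.

Two curated models ship with the package:

* :func:`egfr_model` — adaptor binding to the phosphorylated EGFR cytoplasmic
  domain. Four phosphotyrosine sites (pY992, pY1068, pY1148, pY1173) mediate
  six binding possibilities for Grb2, PLCg1, Stat5 and Shc; three blocking
  state variables (bndPLCg992, bndPLCg1173, bndSHC1148) encode the reported
  mutual-exclusion constraints between PLCg1 and Shc binding. 11 complex
  species, 6 association rules. Receptor dimerization is deliberately out of
  scope of this small model.

* :func:`gprotein_model` — a ligand/receptor/heterotrimeric G-protein cycle:
  receptor ligation and ligand dissociation, G-protein recruitment to the
  ligated receptor, receptor-catalyzed GDP/GTP exchange, trimer dissociation
  into Galpha-GTP and Gbg, GTP hydrolysis and trimer reassembly, plus a
  receptor-recycling and an effector-activation transformation. 8 complex
  species, 11 rules (3 associations, 4 dissociations, 4 transformations).
  Only the ligation, dissociation and GDP/GTP-exchange rules are mechanistic
  anchors; the remaining rules complete the cycle and are marked with
  provenance ``fixture-completion`` in the model metadata.

:func:`random_model` generates arbitrary valid models as a pure function of a
:class:`RandomModelSpec`; it backs the property-test suites.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .model import (
    BindingSiteRef,
    Complex,
    ComplexSpecies,
    Model,
    Molecule,
    Component,
    NetviewError,
    ReactionRule,
    RuleCategory,
    TriState,
)

ON = TriState.ON
OFF = TriState.OFF
DC = TriState.DONT_CARE

A = RuleCategory.ASSOCIATION
D = RuleCategory.DISSOCIATION
T = RuleCategory.TRANSFORMATION


class GenerationError(NetviewError):
    """Raised for infeasible random-model specifications."""


def egfr_model() -> Model:
    """EGFR cytoplasmic-domain adaptor-binding model (11 species, 6 rules).

    The EGFR species carries five binding sites — sites 1-4 are the adaptor
    sites pY992, pY1068, pY1148, pY1173; site 5 is an unused membrane-anchor
    site — and three state variables implementing the binding constraints:

    * PLCg1 binds pY992 only when bndPLCg992 and bndPLCg1173 are both off
      (product switches bndPLCg992 on);
    * PLCg1 binds pY1173 only when all three variables are off (product
      switches bndPLCg1173 on);
    * Shc binds pY1148 only when bndSHC1148 and bndPLCg1173 are off (product
      switches bndSHC1148 on);
    * Grb2 (pY1068), Stat5 (pY992) and Shc at pY1173 bind unconditionally.
    """
    egfr_states = ("bndPLCg992", "bndPLCg1173", "bndSHC1148")
    molecules = (
        Molecule("EGFR", (
            Component("cytoplasmic",
                      state_variables=egfr_states,
                      binding_sites=("pY992", "pY1068", "pY1148", "pY1173",
                                     "anchor")),
        )),
        Molecule("Grb2", (Component("SH2", binding_sites=("sh2",)),)),
        Molecule("PLCg1", (Component("SH2", binding_sites=("sh2",)),)),
        Molecule("Stat5", (Component("SH2", binding_sites=("sh2",)),)),
        Molecule("Shc", (Component("PTB", binding_sites=("ptb",)),)),
    )

    def egfr_cx(name: str, v992: TriState, v1173: TriState, v1148: TriState,
                species: str = "EGFR") -> Complex:
        return Complex(name, species, {
            ("egfr", "cytoplasmic", "bndPLCg992"): v992,
            ("egfr", "cytoplasmic", "bndPLCg1173"): v1173,
            ("egfr", "cytoplasmic", "bndSHC1148"): v1148,
        })

    adaptors = ("Grb2", "PLCg1", "Stat5", "Shc")
    unbound_species = [
        ComplexSpecies(
            "EGFR",
            molecule_instances=(("egfr", "EGFR"),),
            complexes=(
                egfr_cx("EGFR unbound", DC, DC, DC),
                egfr_cx("EGFR PLCg sites free", OFF, OFF, DC),
                egfr_cx("EGFR adaptor free", OFF, OFF, OFF),
                egfr_cx("EGFR Shc sites free", DC, OFF, OFF),
            ),
        )
    ] + [
        ComplexSpecies(
            name,
            molecule_instances=((name.lower(), name),),
            complexes=(Complex(name, name, {}),),
        )
        for name in adaptors
    ]

    # one bound-complex species per binding possibility; the EGFR instance is
    # declared first so EGFR site indices 1-5 carry over into the product
    site_of = {"pY992": 1, "pY1068": 2, "pY1148": 3, "pY1173": 4}
    bindings = (
        # (adaptor, site, reactant EGFR complex, product states)
        ("Stat5", "pY992", "EGFR unbound", (DC, DC, DC)),
        ("Grb2", "pY1068", "EGFR unbound", (DC, DC, DC)),
        ("PLCg1", "pY992", "EGFR PLCg sites free", (ON, OFF, DC)),
        ("PLCg1", "pY1173", "EGFR adaptor free", (OFF, ON, OFF)),
        ("Shc", "pY1148", "EGFR Shc sites free", (DC, OFF, ON)),
        ("Shc", "pY1173", "EGFR unbound", (DC, DC, DC)),
    )

    bound_species = []
    rules = []
    for adaptor, site, reactant_cx, product_states in bindings:
        sp_name = f"EGFR_{adaptor}_{site}"
        bound_species.append(
            ComplexSpecies(
                sp_name,
                molecule_instances=(("egfr", "EGFR"), (adaptor.lower(), adaptor)),
                structural_bonds=((site_of[site], 6),),
                complexes=(egfr_cx("bound", *product_states, species=sp_name),),
            )
        )
        rules.append(
            ReactionRule(
                name=f"{adaptor} binds {site}",
                category=A,
                reactants=(("EGFR", reactant_cx), (adaptor, adaptor)),
                products=((sp_name, "bound"),),
                bond_sites=(
                    BindingSiteRef("EGFR", site_of[site]),
                    BindingSiteRef(adaptor, 1),
                ),
                rate_constant=1.0,
            )
        )

    return Model(
        molecules=molecules,
        species=tuple(unbound_species + bound_species),
        rules=tuple(rules),
        metadata={
            "name": "EGFR adaptor binding",
            "description": "Simultaneous vs. exclusive adaptor binding to the "
                           "phosphorylated EGFR cytoplasmic domain",
        },
    )


_GPROTEIN_VERBATIM = (
    "receptor ligation",
    "ligand dissociation",
    "Receptor mediated Galpha GDP GTP exchange",
)


def gprotein_model() -> Model:
    """Ligand/receptor/G-protein cycle model (8 species, 11 rules)."""
    molecules = (
        Molecule("Ligand", (Component("core", binding_sites=("rec",)),)),
        Molecule("Receptor", (
            Component("extracellular", binding_sites=("lig",)),
            Component("intracellular", state_variables=("active",),
                      binding_sites=("gprot",)),
        )),
        Molecule("Galpha", (
            Component("Ga", state_variables=("GTP",),
                      binding_sites=("rec", "gbg")),
        )),
        Molecule("Gbg", (Component("Gbg", binding_sites=("ga",)),)),
        Molecule("Effector", (
            Component("catalytic", state_variables=("active",),
                      binding_sites=("ga",)),
        )),
    )

    def rec_state(value: TriState) -> dict:
        return {("rec", "intracellular", "active"): value}

    species = (
        ComplexSpecies("Ligand", (("lig", "Ligand"),),
                       complexes=(Complex("Ligand", "Ligand", {}),)),
        ComplexSpecies("Receptor", (("rec", "Receptor"),),
                       complexes=(
                           Complex("Rec inactive", "Receptor", rec_state(OFF)),
                           Complex("Receptor_2", "Receptor", rec_state(OFF)),
                           Complex("Rec inactive unbound", "Receptor",
                                   rec_state(OFF)),
                       )),
        # sites: 1 = lig.rec, 2 = rec.extracellular, 3 = rec.intracellular
        ComplexSpecies("Ligated Receptor",
                       (("lig", "Ligand"), ("rec", "Receptor")),
                       structural_bonds=((1, 2),),
                       complexes=(Complex("Ligated Receptor", "Ligated Receptor",
                                          rec_state(ON)),)),
        # sites: 1 = ga.rec, 2 = ga.gbg, 3 = gbg.ga
        ComplexSpecies("Gabg", (("ga", "Galpha"), ("gbg", "Gbg")),
                       structural_bonds=((2, 3),),
                       complexes=(
                           Complex("Gabg_GDP", "Gabg",
                                   {("ga", "Ga", "GTP"): OFF}),
                           Complex("Gabg_GTP", "Gabg",
                                   {("ga", "Ga", "GTP"): ON}),
                       )),
        # sites: 1 lig.rec, 2 rec.ext, 3 rec.intra, 4 ga.rec, 5 ga.gbg, 6 gbg.ga
        ComplexSpecies("LigRec_Gabg",
                       (("lig", "Ligand"), ("rec", "Receptor"),
                        ("ga", "Galpha"), ("gbg", "Gbg")),
                       structural_bonds=((1, 2), (3, 4), (5, 6)),
                       complexes=(
                           Complex("LigRec_Gab_GDP", "LigRec_Gabg",
                                   {**rec_state(ON), ("ga", "Ga", "GTP"): OFF}),
                           Complex("LigRec_Gabg_GTP", "LigRec_Gabg",
                                   {**rec_state(ON), ("ga", "Ga", "GTP"): ON}),
                       )),
        ComplexSpecies("Galpha", (("ga", "Galpha"),),
                       complexes=(
                           Complex("Galpha_GTP", "Galpha",
                                   {("ga", "Ga", "GTP"): ON}),
                           Complex("Galpha_GDP", "Galpha",
                                   {("ga", "Ga", "GTP"): OFF}),
                       )),
        ComplexSpecies("Gbg", (("gbg", "Gbg"),),
                       complexes=(Complex("Gbg", "Gbg", {}),)),
        ComplexSpecies("Effector", (("eff", "Effector"),),
                       complexes=(
                           Complex("Effector inactive", "Effector",
                                   {("eff", "catalytic", "active"): OFF}),
                           Complex("Effector active", "Effector",
                                   {("eff", "catalytic", "active"): ON}),
                       )),
    )

    ref = BindingSiteRef
    rules = (
        ReactionRule("receptor ligation", A,
                     reactants=(("Ligand", "Ligand"), ("Receptor", "Rec inactive")),
                     products=(("Ligated Receptor", "Ligated Receptor"),),
                     bond_sites=(ref("Ligand", 1), ref("Receptor", 1)),
                     rate_constant=1.0),
        ReactionRule("ligand dissociation", D,
                     reactants=(("Ligated Receptor", "Ligated Receptor"),),
                     products=(("Ligand", "Ligand"), ("Receptor", "Rec inactive")),
                     bond_sites=(ref("Ligated Receptor", 1),
                                 ref("Ligated Receptor", 2)),
                     rate_constant=0.1),
        ReactionRule("Receptor mediated Galpha GDP GTP exchange", T,
                     reactants=(("LigRec_Gabg", "LigRec_Gab_GDP"),),
                     products=(("LigRec_Gabg", "LigRec_Gabg_GTP"),),
                     rate_constant=2.0),
        ReactionRule("G protein recruitment", A,
                     reactants=(("Ligated Receptor", "Ligated Receptor"),
                                ("Gabg", "Gabg_GDP")),
                     products=(("LigRec_Gabg", "LigRec_Gab_GDP"),),
                     bond_sites=(ref("Ligated Receptor", 3), ref("Gabg", 1)),
                     rate_constant=1.0),
        ReactionRule("G protein release", D,
                     reactants=(("LigRec_Gabg", "LigRec_Gabg_GTP"),),
                     products=(("Ligated Receptor", "Ligated Receptor"),
                               ("Gabg", "Gabg_GTP")),
                     bond_sites=(ref("LigRec_Gabg", 3), ref("LigRec_Gabg", 4)),
                     rate_constant=1.0),
        ReactionRule("basal G protein dissociation", D,
                     reactants=(("LigRec_Gabg", "LigRec_Gab_GDP"),),
                     products=(("Ligated Receptor", "Ligated Receptor"),
                               ("Gabg", "Gabg_GDP")),
                     bond_sites=(ref("LigRec_Gabg", 3), ref("LigRec_Gabg", 4)),
                     rate_constant=0.05),
        ReactionRule("trimer dissociation", D,
                     reactants=(("Gabg", "Gabg_GTP"),),
                     products=(("Galpha", "Galpha_GTP"), ("Gbg", "Gbg")),
                     bond_sites=(ref("Gabg", 2), ref("Gabg", 3)),
                     rate_constant=1.0),
        ReactionRule("trimer reassociation", A,
                     reactants=(("Galpha", "Galpha_GDP"), ("Gbg", "Gbg")),
                     products=(("Gabg", "Gabg_GDP"),),
                     bond_sites=(ref("Galpha", 2), ref("Gbg", 1)),
                     rate_constant=1.0),
        ReactionRule("GTP hydrolysis", T,
                     reactants=(("Galpha", "Galpha_GTP"),),
                     products=(("Galpha", "Galpha_GDP"),),
                     rate_constant=0.5),
        ReactionRule("receptor recycling", T,
                     reactants=(("Receptor", "Receptor_2"),),
                     products=(("Receptor", "Rec inactive unbound"),),
                     rate_constant=0.2),
        ReactionRule("effector activation", T,
                     reactants=(("Effector", "Effector inactive"),),
                     products=(("Effector", "Effector active"),),
                     rate_constant=1.0),
    )

    return Model(
        molecules=molecules,
        species=species,
        rules=rules,
        metadata={
            "name": "G-protein signaling",
            "description": "Ligand/receptor/heterotrimeric G-protein cycle",
            "rule_provenance": {
                r.name: ("anchor" if r.name in _GPROTEIN_VERBATIM
                         else "fixture-completion")
                for r in rules
            },
        },
    )


@dataclass(frozen=True)
class RandomModelSpec:
    """Parameters of the seeded random-model generator.

    Generation is a pure function of the spec: equal specs yield equal
    models. ``category_weights`` orders as (association, dissociation,
    transformation) and must not be all zero.
    """

    n_species: int
    n_rules: int = 0
    category_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    max_sites_per_species: int = 3
    max_state_vars: int = 2
    seed: int = 0


def random_model(spec: RandomModelSpec) -> Model:
    """Generate a valid model from a :class:`RandomModelSpec`.

    Every species holds one molecule instance with 1..max_sites binding
    sites, 0..max_state_vars state variables and 1-3 declared complexes with
    arbitrary tri-state maps (stored complexes may use don't-care). Rules
    draw their category from ``category_weights`` and reference uniformly
    chosen declared complexes, respecting category arity; reactant species
    repetition (homotypic rules) is allowed.
    """
    if spec.n_species < 0 or spec.n_rules < 0:
        raise GenerationError("n_species and n_rules must be non-negative")
    if spec.n_rules > 0 and spec.n_species == 0:
        raise GenerationError("cannot generate rules without species")
    if spec.max_sites_per_species < 1:
        raise GenerationError("max_sites_per_species must be positive")
    if len(spec.category_weights) != 3 or any(w < 0 for w in spec.category_weights) \
            or not any(spec.category_weights):
        raise GenerationError("category_weights must be 3 non-negative reals, "
                              "not all zero")

    rng = random.Random(spec.seed)
    molecules = []
    species = []
    for i in range(spec.n_species):
        n_sites = rng.randint(1, spec.max_sites_per_species)
        n_vars = rng.randint(0, spec.max_state_vars)
        mol = Molecule(
            f"M{i}",
            (Component(
                "c0",
                state_variables=tuple(f"v{k}" for k in range(n_vars)),
                binding_sites=tuple(f"s{k}" for k in range(n_sites)),
            ),),
        )
        molecules.append(mol)
        keys = [(f"m{i}", "c0", f"v{k}") for k in range(n_vars)]
        complexes = tuple(
            Complex(
                f"S{i}_c{k}",
                f"S{i}",
                {key: rng.choice((ON, OFF, DC)) for key in keys},
            )
            for k in range(rng.randint(1, 3))
        )
        species.append(
            ComplexSpecies(f"S{i}", ((f"m{i}", f"M{i}"),), (), complexes)
        )

    def pick_ref() -> tuple[str, str]:
        sp = rng.choice(species)
        return sp.name, rng.choice(sp.complexes).name

    def pick_site(species_name: str) -> BindingSiteRef:
        idx = int(species_name[1:])
        n_sites = len(molecules[idx].components[0].binding_sites)
        return BindingSiteRef(species_name, rng.randint(1, n_sites))

    categories = (A, D, T)
    rules = []
    for i in range(spec.n_rules):
        cat = rng.choices(categories, weights=spec.category_weights)[0]
        n_react, n_prod = {A: (2, 1), D: (1, 2), T: (1, 1)}[cat]
        reactants = tuple(pick_ref() for _ in range(n_react))
        products = tuple(pick_ref() for _ in range(n_prod))
        bond_sites = None
        if cat is A:
            bond_sites = (pick_site(reactants[0][0]), pick_site(reactants[1][0]))
        elif cat is D:
            sp_name = reactants[0][0]
            n_sites = len(molecules[int(sp_name[1:])].components[0].binding_sites)
            if n_sites >= 2:
                a, b = rng.sample(range(1, n_sites + 1), 2)
                bond_sites = (BindingSiteRef(sp_name, a), BindingSiteRef(sp_name, b))
        rules.append(
            ReactionRule(
                f"R{i}", cat, reactants, products, bond_sites,
                rate_constant=round(rng.uniform(0.0, 10.0), 3),
            )
        )

    return Model(
        molecules=tuple(molecules),
        species=tuple(species),
        rules=tuple(rules),
        metadata={"name": f"random(seed={spec.seed})"},
    )
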
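# netview

Bipartite species–reaction network graphs for **rule-based models of
multi-component, multi-state molecular complexes** — construction, layout,
tri-state pattern queries, and SVG/DOT/GraphML export.

## Who this is for

Modelers of cellular signaling who describe their systems with reaction
rules over *complex species* — structural prototypes built from molecules,
components, binding sites and tri-state state variables (`on` / `off` /
`don't care`) — and who want a compact, queryable network view of the rule
set: which species react with which, through which binding sites, and under
which state conditions. Rates are stored with the rules but never
integrated; this is a network-structure tool, not a simulator.

## The core model

A model holds molecules, complex species (each with a curated list of
*complexes*, i.e. concrete tri-state assignments), and reaction rules in
exactly three categories with fixed arities:

| category       | reactants → products | bond change      |
|----------------|----------------------|------------------|
| association    | 2 → 1                | forms a bond     |
| dissociation   | 1 → 2                | dissolves a bond |
| transformation | 1 → 1                | none (states only) |

The **network graph** is directed and bipartite: one node per complex
species, one *intermediate* node per reaction rule, one edge per
reactant occurrence (species → reaction) and per product occurrence
(reaction → species). Hence, for `S` species and `R` rules with `A`
associations, `D` dissociations and `T` transformations:

```
n_nodes = S + R          n_edges = 3·(A + D) + 2·T
```

Association/dissociation edges are anchored at the binding sites they
involve; transformation edges point at species-node centers. Three layout
modes are provided (force-directed; level-based by *reaction distance* to a
reference species; circular as the polar conversion of the level layout),
all overlap-free and seed-deterministic, with persistence to an auxiliary
JSON file. The query engine implements case-insensitive name filtering,
hereditary molecule filtering, symmetric three-valued state matching and
reaction/complex selection with rendering overlays.

## Worked example

Two curated models ship in `netview.fixtures`: a ligand/receptor/G-protein
cycle and an EGFR adaptor-binding model in which four phosphotyrosine
sites (pY992, pY1068, pY1148, pY1173) mediate six binding possibilities
for Grb2, PLCγ1, Stat5 and Shc, with mutual-exclusion constraints encoded
in three blocking state variables.

```python
from netview import (build_network_graph, egfr_model, graph_stats,
                     search_species, StatePattern, TriState)

model = egfr_model()
graph = build_network_graph(model)
print(graph_stats(graph).to_dict())

res = search_species(model, graph, StatePattern.of(
    "EGFR", {("egfr", "cytoplasmic", "bndPLCg992"): TriState.ON}))
print(sorted(r for r in res.highlighted_rules if "PLCg1" in r))
```

prints

```
{'n_species_nodes': 11, 'n_reaction_nodes': 6, 'n_nodes': 17, 'n_edges': 18,
 'per_category': {'association': 6, 'dissociation': 0, 'transformation': 0}}
[]
```

— 11 species and 6 association rules produce a 17-node, 18-edge graph, and
once a PLCγ1 occupies pY992 (state `bndPLCg992 = on`), *no* PLCγ1
association remains reachable: the encoded binding constraint is verified
straight from the network view. The `examples/` directory contains one
short narrative script per capability (graph statistics, layouts, queries,
rendering/export); each prints the numbers it computes.

A thin CLI wraps the library:

```bash
netview fixtures --name gprotein -o gp.json
netview stats gp.json
netview layout gp.json --mode circular --reference Ligand -o lay.json
netview search gp.json --species Receptor --state intracellular.active:off
netview render gp.json --layout lay.json -o gp.svg
```

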
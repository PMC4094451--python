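"""Filters, tri-state state search and selections.

The search uses three-valued matching: a query value of on/off matches the
same stored value, and don't-care (on either side) matches anything. This
is how binding constraints encoded in state variables can be *verified*
from the network view: search for the blocking state and see which
reactions stay dark.
"""

from netview import (
    StatePattern,
    TriState,
    build_network_graph,
    egfr_model,
    filter_by_molecule,
    filter_by_name,
    gprotein_model,
    search_species,
    select_complex,
)

gprot = gprotein_model()
ggraph = build_network_graph(gprot)

print("filter by name 'gdp':")
rep = filter_by_name(gprot, "gdp")
print(f"  matching complexes      : {sorted(rep.matching_complexes())}")
print(f"  species with child match: "
      f"{[n for n, h in rep.species.items() if h.value == 'child_match']}")

print("\nfilter by molecule 'Ligand':")
print(f"  species containing it: {sorted(filter_by_molecule(gprot, 'Ligand').matching_species())}")

print("\nsearch Receptor for intracellular state off:")
res = search_species(gprot, ggraph, StatePattern.of(
    "Receptor", {("rec", "intracellular", "active"): TriState.OFF}))
print(f"  matching complexes : {list(res.matched_complexes)}")
print(f"  highlighted rules  : {sorted(res.highlighted_rules)}")

print("\nselect complex Rec inactive:")
sel = select_complex(gprot, ggraph, ("Receptor", "Rec inactive"))
print(f"  participates in {len(sel.highlighted_rules)} reactions: "
      f"{sorted(sel.highlighted_rules)}")

# verify an EGFR binding constraint: with a PLCg1 already on pY992,
# no further PLCg1 association can fire
egfr = egfr_model()
egraph = build_network_graph(egfr)
res = search_species(egfr, egraph, StatePattern.of(
    "EGFR", {("egfr", "cytoplasmic", "bndPLCg992"): TriState.ON}))
plcg = {r for r in res.highlighted_rules if "PLCg1" in r}
print(f"\nEGFR with bndPLCg992=on: PLCg1 associations highlighted = {sorted(plcg)}")
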
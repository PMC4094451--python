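"""The three layout modes and the auxiliary layout file.

Level-based and circular layouts organize the network by *reaction
distance* to a reference species: the minimal number of reactions linking a
species to the reference. The circular layout is the polar conversion of
the level layout, so the two agree on levels/rings by construction.
"""

import math

from netview import (
    build_network_graph,
    gprotein_model,
    layout_circular,
    layout_force,
    layout_level,
    reaction_distance,
    save_layout,
)

graph = build_network_graph(gprotein_model())

levels = reaction_distance(graph, "Ligand")
print("reaction distance from Ligand:")
for sp, lv in sorted(levels.levels.items(), key=lambda kv: (kv[1], kv[0])):
    print(f"  level {lv}: {sp}")
print(f"  unreachable: {sorted(levels.unreachable)}")

force = layout_force(graph, seed=1)
level = layout_level(graph, "Ligand")
circ = layout_circular(graph, "Ligand")

print(f"\nlevel layout: Ligand sits at the top, y = "
      f"{level.positions['Ligand'][1]:.0f}")
print(f"circular layout: Ligand at the centre {circ.positions['Ligand']}, "
      f"Gbg at radius {math.hypot(*circ.positions['Gbg']):.0f}")

# persist the layout (plus a manual edge-width emphasis) for later reuse
circ.visual_overrides["edge:receptor ligation::reactant::Ligand::0"] = \
    {"width": 4.0}
text = save_layout(circ, graph)
print(f"\nauxiliary layout file: {len(text)} bytes of JSON")
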
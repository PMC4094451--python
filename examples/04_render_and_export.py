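"""Render the network to SVG and export DOT/GraphML.

Edges are cubic Béziers in the category hue (association green,
dissociation orange, transformation purple) with saturation rising from the
reactant toward the product end; association/dissociation edges touch the
involved binding-site circles, transformation edges the species centres.
Selecting a reaction overlays the rule-side complexes onto the species
glyphs.
"""

from pathlib import Path

from netview import (
    build_network_graph,
    export_dot,
    export_graphml,
    gprotein_model,
    layout_force,
    render_svg,
    select_reaction,
)

model = gprotein_model()
graph = build_network_graph(model)
layout = layout_force(graph, seed=1)

out = Path("scratch") if Path("scratch").is_dir() else Path(".")

svg = render_svg(graph, layout)
(out / "gprotein.svg").write_text(svg)
print(f"overview SVG: {len(svg)} bytes -> {out / 'gprotein.svg'}")

selection = select_reaction(model, graph, "receptor ligation")
svg_sel = render_svg(graph, layout, selection=selection)
(out / "gprotein_ligation.svg").write_text(svg_sel)
print(f"with 'receptor ligation' selected: overlays on "
      f"{sorted(selection.overlays)}")

dot = export_dot(graph)
gml = export_graphml(graph)
print(f"DOT export    : {len(dot.splitlines())} lines")
print(f"GraphML export: {len(gml.splitlines())} lines")
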
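"""Build a bipartite species-reaction graph and read off its statistics.

The EGFR adaptor-binding model declares 11 complex species (the receptor
domain, four adaptors and one bound complex per binding possibility) and 6
association rules. The network graph gets one node per species, one node
per rule, and one edge per reactant/product occurrence — so an association
(2 reactants, 1 product) contributes 3 edges.
"""

from netview import build_network_graph, egfr_model, graph_stats

model = egfr_model()
graph = build_network_graph(model)
stats = graph_stats(graph)

print(f"species            : {len(model.species)}")
print(f"reaction rules     : {len(model.rules)}")
print(f"graph nodes        : {stats.n_nodes}   (= species + rules)")
print(f"graph edges        : {stats.n_edges}   (= 3(A+D) + 2T)")
print(f"rules per category : {stats.per_category}")

# the four adaptor sites of the EGFR cytoplasmic domain
for site in model.site_table("EGFR")[:4]:
    print(f"EGFR site {site.index}: {site.site_name}")
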
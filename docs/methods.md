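# Methods

## The modelling language

`netview` operates on rule-based models in the contact-map tradition:

* **Molecule** — a named entity built from **components** (sub-domains).
  Each component declares ordered **binding sites** and **state
  variables**. A state variable is a binary biochemical flag
  (phosphorylation, conformation, nucleotide load, …) that queries and rule
  patterns may additionally leave as *don't care*; the three values
  serialize as `on` / `off` / `dont_care`.
* **Complex species** — a structural prototype: an ordered multiset of
  molecule instances plus a set of structural bonds between binding sites.
  Binding sites are indexed **1-based per species in declaration order**
  across molecule instances and their components; a site participates in at
  most one structural bond. The numbering scheme is a package convention:
  displayed site indices are shown inside the site circles, and keeping the
  first instance's indices stable means an unbound species' site indices
  carry over into any bound species that declares it first.
* **Complex** — an instance of its species: a *total* tri-state assignment
  over every state variable the species' molecules declare. Complexes are
  explicitly declared per species (a curated list), not enumerated
  combinatorially from the state variables; rule-side complexes are
  patterns and may use don't-care.
* **Reaction rule** — a categorized rewrite of declared complexes:
  association (2 reactants → 1 product, forms a bond), dissociation
  (1 → 2, dissolves a bond), transformation (1 → 1, state change only).
  `bond_sites` names the two sites whose bond is formed (one per reactant
  species) or dissolved (both in the reactant species); transformations
  never carry bond sites. The rate constant is a single non-negative number
  stored verbatim — units are opaque and nothing integrates kinetics.

### Document format

Models are versioned JSON (YAML is accepted as a reading dialect producing
identical models); the structural contract ships as a draft-07 style schema
in `src/netview/schema/model.schema.json`, and the reader enforces it with
a structural checker that reports JSON-pointer paths. Unknown keys are
ignored with a logged warning so documents from richer toolchains load.
Serialization is canonical — entity lists sorted by name, object keys
alphabetical — so models with equal content produce byte-identical output
regardless of construction order; model equality is defined accordingly.

Validation is complete rather than fail-fast: `validate_model` returns
every violation as data with a machine-readable code (`ARITY`,
`DANGLING_REF`, `STATE_COVERAGE`, `BOND_ON_TRANSFORM`, `SITE_INDEX`,
`BOND_SITE_REUSE`, `BOND_SITE_SPECIES`, `DUP_NAME`, `NEGATIVE_RATE`) and
the offending entity path. Two complexes of one species with identical
state maps are flagged as a **warning** (`DUP_STATE_MAP`), not an error:
structurally identical complexes that differ only in name are meaningful
when they play different roles in different rules (the packaged G-protein
model's receptor complexes exercise this deliberately).

## The bipartite network graph

One node per complex species, one intermediate node per rule; a reactant
occurrence contributes a species→reaction edge, a product occurrence a
reaction→species edge. Consequently `n_nodes = S + R` and
`n_edges = 3(A + D) + 2T`, both checked as exact invariants. Homotypic
rules (the same species occurring twice on one side) produce two parallel
edges distinguished by `occurrence_index`, which keeps the edge-count
formula exact and is the reading we adopt where an existential phrasing
("an edge exists iff the species is involved") would be ambiguous.

**Edge anchoring.** Transformation edges anchor at species centers
(`anchor = None`). Association reactant edges anchor at the rule's bond
site for that species (occurrences consume the matching bond sites in rule
order, so homotypic reactants get distinct anchors). The association
*product* edge anchors at the newly formed bond's lower-indexed site; the
new bond is identified structurally as the unique structural bond of the
product species whose removal splits its instance graph into two connected
components whose molecule multisets equal the two reactants'. When no
unique such bond exists (e.g. arbitrary random-model products), the edge
falls back to the center. Dissociation reactant edges anchor at the
lower-indexed dissolved site; dissociation product edges anchor at the
center, because the model format carries no instance correspondence
between rule sides from which the freed product-side sites could be
recovered — a deliberate scope cut.

Species and rules share the graph's node-id namespace (plain names, as in
the rendered figures); graph construction rejects a model in which a
species and a rule share a name.

## Layouts

All layouts are pure functions of `(graph, mode, reference, seed, params)`
in abstract, pixel-like canvas units (y grows downward for force/level;
circular is centered at the origin with the mathematical angle convention).
Node boxes come from the same glyph geometry the renderer draws, so
overlap removal operates on what is actually displayed.

* **Force** — `networkx` spring embedding (seeded, hence deterministic),
  scaled by √n times the mean node diagonal, followed by iterative
  pairwise box separation along the connecting vector (at most 500
  iterations, 10⁻⁶ canvas-unit tolerance, 6-unit clearance). Single nodes
  sit at the origin.
* **Level** — *reaction distance* levels from a breadth-first search over
  the undirected bipartite graph: a species' level is half its bipartite
  path length (always an integer), a reaction node sits at the minimal
  adjacent species level + 0.5. `y = level × spacing` with the spacing
  auto-raised to twice the tallest box plus clearance so consecutive
  half-level bands cannot collide; within a band, nodes order by a
  barycenter heuristic over already-placed lower-level neighbours with
  name tie-breaks, and are slotted side by side by their actual widths.
  Unreachable nodes go to a trailing band two levels below the deepest
  reachable one. The barycenter + name tie-break is a package choice — a
  hierarchical layouter with different sweep heuristics will order bands
  differently, so exact figure geometry from other tools is not
  reproduced, only the level structure.
* **Circular** — polar conversion of the level layout: radius = level ×
  ring spacing (reference fixed at the center), initial angle
  `2π·(x − x_min)/(x_max − x_min + gutter)` from the level-layout
  abscissa. Ring spacing is raised until consecutive half-level rings
  clear each other and every ring has circumference for its members at 60%
  angular fill; a per-ring, order-preserving minimum-gap pass (with a
  cumulative redistribution fallback for crowded rings) removes residual
  overlaps without disturbing the within-ring left-to-right order. Radii
  are therefore *exactly* level × spacing: equal-level species share a
  radius to machine precision and radius is strictly monotone in level.

**Persistence.** `save_layout`/`load_layout` round-trip positions
bit-exactly (JSON doubles), along with sizes, mode, reference and free-form
visual attribute overrides such as per-edge widths. Loading against a graph
whose node set changed is not fatal: known positions are kept untouched,
new nodes are placed by a spring pass with all known nodes held fixed, and
both groups are reported in a reconciliation diff (the CLI's `render`
refuses a mismatched layout with exit code 1 unless `--reconcile` is
given). Manual adjustment is API-level: edit `Layout.positions` /
`visual_overrides` and save.

## Queries and selection semantics

* **Name filter** — case-insensitive substring on species and complex
  names (no regular expressions). A species whose own name misses the term
  but that has a matching child complex is reported `CHILD_MATCH` (the
  light-blue collapsed-list hint); complexes are `MATCH`/`NONE`.
* **Molecule filter** — hereditary: a complex contains a molecule iff its
  species does, because all complexes of a species are structurally
  identical; species and all their complexes therefore always share the
  highlight state and `CHILD_MATCH` cannot occur.
* **Tri-state matching** — symmetric: per variable, don't-care on either
  side matches, otherwise values must agree. The query-side rule (a query
  don't-care matches stored on/off) is the interactive-search behaviour;
  extending it symmetrically keeps rule-pattern complexes — which
  legitimately store don't-care — searchable. This symmetry is a deliberate
  package decision.
* **State search** — restricted to the pattern's species (the red-bordered
  glyph); unconstrained variables default to don't-care. The result
  carries the matching complexes, every rule having one of them as
  reactant or product, and all edges incident to those rules.
* **Selections** — selecting a rule highlights exactly its incident edges;
  associations/dissociations overlay each involved species node with its
  rule-side complex (states plus bond status at the rule's bond sites,
  complex name as a blue sublabel), transformations carry a detached
  before/after pair rendered as a side panel. Selecting a complex
  highlights the rules listing it.

Identifier cross-references are case-sensitive (deterministic linking);
only the name *filter* is case-insensitive.

## Rendering and export

SVG output is deterministic (stable element order and id scheme). Species
glyphs draw one ellipse per component (instances side by side, components
stacked), site circles on the ellipse boundary with the index inside
(filled when bound, bonded pairs joined by blue lines), and one square per
state variable — filled = on, open = off, half-filled = don't care (the
half-fill is this package's rendering of the wildcard glyph). Edges are
cubic Béziers with control points at 1/3 and 2/3 of the chord, offset
perpendicularly by 15% of the chord length with the sign alternating by
occurrence index so parallel edges separate. The reactant→product
saturation gradient is realized by splitting each curve into 8 de
Casteljau segments with per-segment solid strokes (SVG has no along-path
gradients); hue and value stay fixed per category — defaults green
(association), orange (dissociation), purple (transformation), freely
overridable via a style JSON. Rate constants are emitted as `<title>`
tooltips on edge groups. Highlighted edges gain width (×2.5) and full
opacity.

DOT export is plain text written directly (node `kind`/`category`, edge
`role`/`anchor_site`/`occurrence`/`edge_id`); GraphML goes through
networkx. Both re-parse to a graph isomorphic to the input, which the test
suite checks with readers that live only in the tests.

## Packaged models

* **G-protein cycle** (8 species, 11 rules: 3 associations, 4
  dissociations, 4 transformations). Receptor ligation, ligand
  dissociation and receptor-catalyzed GDP/GTP exchange are the mechanistic
  anchors; recruitment/release of the heterotrimer, basal dissociation,
  trimer dissociation/reassembly, GTP hydrolysis, receptor recycling and a
  (disconnected) effector activation complete the cycle and are tagged
  `fixture-completion` in the model metadata so tests can separate core
  mechanism from scaffolding. The category split satisfies
  3(A+D) + 2T = 29 edges over 19 nodes.
* **EGFR adaptor binding** (11 species, 6 association rules). The receptor
  cytoplasmic domain has five binding sites — four adaptor sites pY992,
  pY1068, pY1148, pY1173 plus an unused membrane-anchor site 5 — and three
  blocking state variables. PLCγ1 binding to either of its two sites
  requires both `bndPLCg992` and `bndPLCg1173` off and switches on the one
  it occupies; Shc at pY1148 additionally requires `bndSHC1148` and
  `bndPLCg1173` off; Grb2, Stat5 and Shc-at-pY1173 bind unconditionally.
  Bound product species are named `EGFR_<Adaptor>_<site>`. Receptor
  dimerization is deliberately out of scope of this small model.

## The random-model generator

`random_model(RandomModelSpec(...))` is a pure function of its spec
(seeded `random.Random`): each species holds one molecule instance with
1–`max_sites_per_species` sites (default 3), 0–`max_state_vars` state
variables (default 2) and 1–3 declared complexes with arbitrary tri-state
maps; rule categories are drawn from `category_weights` and reference
uniformly chosen declared complexes, allowing homotypic reactants. It
emulates the *combinatorial shape* of rule-based models — arities,
cross-references, tri-state maps, parallel edges — not their biochemistry:
generated products bear no structural relation to their reactants, so
association product edges in random models mostly anchor at centers, and
no statement about real signaling topologies follows from these tests.
What the passing property suites do establish: the count formulas and
bipartiteness hold for every valid model, queries agree with brute-force
scans, layouts are deterministic and overlap-free, and exports round-trip.

## Numerical and degenerate-input choices

* Overlap removal: pairwise separation along the connecting vector, step
  chosen as the smaller single-axis clearing distance plus 10⁻³; a
  deterministic pseudo-angle resolves coincident centers; 500-iteration
  cap with 10⁻⁶ tolerance.
* Level/circular layouts require a reference species node and raise a
  lookup error otherwise; disconnected nodes never abort a layout (trailing
  band / outer ring).
* Empty models are valid throughout: empty graph, empty layouts, valid
  empty exports.
* Seeds are plain integers fed to `networkx`/`random`; every seeded
  operation is reproducible bit-for-bit.

## Known limitations

* No structural (bond-topology) pattern matching beyond declared
  complexes, no rule inference, no reachability or stoichiometry analysis,
  no kinetic simulation.
* Dissociation product edges anchor at species centers (no cross-side
  instance correspondence in the format).
* No edge-crossing minimization; label de-overlap is limited to node
  overlap removal.
* The tool does not import other rule-based model interchange formats;
  the JSON dialect documented by the in-repo schema is the only reader.
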
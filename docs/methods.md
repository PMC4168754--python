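# Methods

## Scope and model

`pathwayviews` models a GPML 2013a pathway as a typed document
(`PathwayDocument`): data nodes carrying a cross-reference, interactions
as ordered point lists whose first and last point are the semantic source
and target, anchors as fractional positions along an interaction, groups,
labels, shapes and modification states. Only the 2013a namespace is
accepted; other namespaces are rejected outright rather than parsed on a
best-effort basis, because the converters' semantics are tied to 2013a
element meanings. States never become graph nodes — they are display
decorations of their parent data node and travel as its attributes.

Coordinates stay in native board units (origin top-left, y down), and
attributes the file omits take fixed defaults (white fill, black border,
z-order 0, solid lines). GPML leaves these to renderers; fixing them
makes style tables deterministic and round-trips exact. Floats are
serialized with their shortest round-tripping representation, which is
what makes the parse∘write∘parse identity hold bit-for-bit.

## Pathway view

The pathway view is a graph whose style table reproduces the diagram:
node x/y equal the GPML centers exactly (no rescaling, no layout). Every
element becomes a node — molecules, annotation nodes for labels and
shapes, group nodes, connector nodes for anchors — so the count identity
|nodes| = |DataNodes| + |Labels| + |Shapes| + |Groups| + |Anchors| holds.
Two geometric quantities GPML does not store are derived:

* **anchors** sit at the linear interpolation between the interaction's
  first and last point at the anchor's position fraction (edge routing
  through intermediate waypoints is renderer cosmetics and is ignored);
* **groups** sit at the bounding-box center of their members.

Interactions with anchors are split into a chain source → anchor… →
target; the terminal segment carries the arrow head. Decorative
graphical lines are kept as undirected edges flagged `graphical=True` so
the view stays lossless, but they are excluded from everything
biological downstream.

### Deferred styles

During conversion, style assignments are recorded into a flat buffer
*before* the target objects necessarily exist, and resolved against the
finished graph in a second pass (`apply_styles`): last write wins,
resolution is idempotent and pure, and a target that never materialized
is a hard error. This two-phase design decouples walking the document
from building the view and makes style application order-independent
apart from the documented last-write-wins rule.

## Network view

Simplification applies four rules: (1) labels, shapes and graphical
lines contribute nothing; (2) data nodes merge by **merge key** — the
xref pair when datasource and identifier are both non-empty, else the
(entity type, text label) pair. Xref identity is the only biologically
sound notion of redundancy; the label fallback covers unannotated nodes.
The merged node's representative attributes come from the first
contributor in document order (a deterministic tie-break), and all
absorbed ids are recorded. (3) Each group becomes one small node joined
to its member molecules by undirected `contains` edges — explicit edges
rather than compound nesting, so that every exporter and metric sees the
containment structure. (4) Each anchor becomes one small connector node
(width = height = 5 board units) splitting its interaction's edge, even
when no third edge attaches to it, preserving the drawn structure.

Parallel edges with identical (endpoints, interaction type, direction)
collapse by default to a single edge with a `multiplicity` attribute —
cleaner for topology metrics; the option `collapse_parallel_edges=False`
keeps them. Edges with an unresolvable endpoint are dropped with a
warning by default (`drop_dangling_edges`); with the option off, a
placeholder connector preserves the stub. An interaction dangling at
both ends disappears entirely.

Merging two copies of the same entity can turn an interaction between
them into a self-loop; the loop is kept in the graph (it is a real
statement about the entity) but ignored by the simple-graph centrality
metrics.

Layout is seeded Fruchterman–Reingold (networkx `spring_layout`, default
seed 42, 100 iterations) on the undirected simple graph with nodes added
in sorted order, which makes the entire conversion — layout included —
reproducible from (document, options). A single node is placed at the
origin. Coordinates live on networkx's unit scale, not in board units;
the network view deliberately abandons the drawn geometry.

## Overlay

Identifier mapping is table-driven: a two-column source → target file
(the workflow BridgeDb serves in interactive tools), with one-to-many
mappings resolved first-by-file-order and counted in an ambiguity
report. The join onto molecule nodes is exact-match on the mapped id,
idempotent, and refuses duplicated identifiers in the data table. When
label-merged nodes carry different xrefs, the representative's value
wins.

The gradient is piecewise-linear per RGB channel over [−L, 0, +L] with
half-up channel rounding; it is continuous, clamps outside ±L, and for
the default palette color(−x) is the exact blue/red mirror of color(+x).
L defaults to max |logFC| over the measured molecules so the palette
always spans the data; it is overridable for cross-dataset
comparability. Significance is **strict** adj-p < α (α = 0.05 default):
a value exactly at α is not highlighted. Unmeasured molecules are grey
`C8C8C8` with the default border; group/connector nodes are never
touched, so measured ⊎ missing partitions exactly the molecule set.

Centrality styling maps degree linearly onto node size [20, 80] (a
constant metric puts all nodes mid-range) and betweenness through the
same gradient machinery, min → low color, max → high color.

## Topology

Degree and betweenness operate on the undirected simple projection
(direction ignored, multiplicity 1, self-loops dropped) — the
convention general-purpose network analyzers apply to mixed graphs.
Betweenness is unnormalized Brandes (networkx), endpoints excluded,
unordered pairs counted once, ties split evenly; a `normalize` flag is
exposed but off by default. The test suite checks it against an
independent brute-force oracle that enumerates every shortest path by
BFS + backtracking on 200 random graphs of ≤ 10 nodes at 1e−9.

## Web-service client

The client's contract, not its transport, is the point: every operation
takes an optional sticky `CancellationToken`. A pre-set token returns
cancelled with zero network calls; a token set mid-transfer is observed
between body chunks (poll interval 50 ms, so well within a 250 ms
latency bound) and aborts the request; the disk cache (keyed by wpid and
revision) is written only after a complete transfer via temp-file +
atomic rename, so cancellation can never leave a partial pathway behind.
The transport is injectable — tests drive the contract with stalled and
canned fake transports and never open a socket — and the default rides
on the standard library with chunked reads. The service base URL,
timeout and cache directory come from a `key=value` config file, since
REST endpoint paths have shifted over the years.

## Synthetic data

The fixture generator emulates the structures the converters must
handle: cross-referenced gene nodes on a grid (with an exact, specified
number of redundant pairs sharing an Entrez Gene id), groups taking
their members from the tail of the node list so grouping and redundancy
don't interact, interactions between distinct nodes with optional
mid-line anchors, plus labels and shapes. Generation is a pure function
of the spec including its seed, and every generated document validates
cleanly.

The companion data generator mirrors a differentiation-experiment
overlay: one row per distinct gene xref, logFC ~ Normal(0, 1.5), a
two-sided normal p-value consistent with the simulated effect size, and
Benjamini–Hochberg adjusted p-values (statsmodels), so the significance
path is exercised with realistic monotonicity (adjusted ≥ raw). The
"unmeasured" fraction (default 0.2, rounded up so it is non-empty
whenever positive) is realized by withholding those genes from the
*mapping* table: the data table stays complete, the affected pathway
nodes simply cannot be mapped to it and take the grey path, and a
fraction of 0 measures every node.

What the generator does **not** emulate: realistic pathway topology
(hub structure, pathway sizes in the hundreds of nodes), multi-source
xrefs, nested groups, curved edge routing, or real expression-data
distributions (its p-values derive deterministically from the effect
sizes). Passing tests therefore demonstrate the conversion and overlay
laws, not performance or robustness on arbitrary curated pathways —
though the parser's unknown-element tolerance is designed for the
latter.

Problem sizes in the shipped suite and acceptance script (50-document
round-trip sweeps, 200 oracle graphs of ≤ 10 nodes, a 9-element
canonical pathway) keep a full run in the low seconds while covering
every code path; all sweeps are seeded and deterministic.

## Known limitations

* GPML 2021 is not read; 2013a only.
* Writing emits the attribute subset the model carries, not every
  optional GPML attribute (schema-perfect emission is a non-goal).
* States and labels referenced by interaction endpoints are dropped in
  the network view (their segments count as dangling).
* Pathway-level merge across documents, active-subnetwork search and
  network extension from interaction databases are out of scope.
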
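# pathwayviews

Biological pathways curated at [WikiPathways](https://www.wikipathways.org)
are stored as GPML — an XML format that describes a *drawing*: gene boxes,
interaction arrows, anchors where one arrow touches another, complexes,
free-text labels and decorative shapes. `pathwayviews` turns a GPML 2013a
document into graphs you can analyze, in two complementary representations:

* **Pathway view** — a graph faithful to the diagram. Every drawn element
  survives (data nodes, labels, shapes, groups, anchors become nodes) and
  every node keeps the exact board coordinates of the original drawing, so
  the layout is identical to the pathway as drawn.
* **Network view** — the abstracted molecular network. Graphical
  annotations are removed, data nodes annotated with the same
  cross-reference (e.g. the same Entrez Gene id drawn twice) are merged
  into one unique node, groups and anchors survive as very small connector
  nodes, and a seeded force-directed layout is applied.

On top of the converters the package provides experimental-data overlay
(log fold-change as a blue–white–red gradient fill, a green border for
adjusted p < α, grey for unmeasured molecules), table-driven identifier
mapping (e.g. Entrez Gene → Ensembl), degree/betweenness centrality,
GraphML/SIF/JSON export, a cancellable WikiPathways web-service client and
a deterministic synthetic-pathway generator for offline testing.

It is aimed at computational biologists who want pathway diagrams as
programmable graph objects — for data visualization in pathway context, or
for topology analysis on the simplified network.

## The core conversions

Merging in the network view is driven by a **merge key** per data node:
the cross-reference pair *(datasource, identifier)* when complete,
otherwise the fallback *(entity type, text label)*. Molecule nodes are in
bijection with distinct merge keys; a merged node records all source
element ids and inherits the attributes of its first contributor in
document order.

Data overlay follows the standard visual mapping: fill color is
piecewise-linear per RGB channel over logFC in [−L, +L] (blue at −L, white
at 0, red at +L, clamped beyond; L defaults to max |logFC|), the border
turns green iff adjusted p-value < α with α = 0.05 **strict**, and
molecules without a measurement are filled grey (`C8C8C8`).

Betweenness is unnormalized shortest-path betweenness (Brandes) on the
undirected simple graph, endpoints excluded, pairs counted once.

## Worked example

```python
from pathwayviews import (
    to_network_view, merge_report, make_demo_data,
    map_identifiers, join_data, apply_data_styles, to_sif,
)
from pathwayviews.fixtures import canonical_fixture

doc = canonical_fixture()           # 5 data nodes (2 share Entrez 1000),
                                    # 1 group of 2, 3 interactions (1 anchored)
graph, styles = to_network_view(doc)
print(len(graph.nodes), len(graph.edges))
print({str(k): v for k, v in merge_report(doc).items()})
print(to_sif(graph))
```

prints

```
6 6
{'xref:Entrez Gene:1000': ['dn0', 'dn1'], 'xref:Entrez Gene:1001': ['dn2'],
 'xref:Entrez Gene:1002': ['dn3'], 'xref:Entrez Gene:1003': ['dn4']}
g0	contains	dn3
g0	contains	dn4
dn2	Arrow	anch0
anch0	Arrow	dn0
dn3	Arrow	dn0
dn0	Arrow	dn0
```

The five data nodes collapse to four molecules (`dn0` absorbed `dn1`);
the group `g0` is a small node tied to its two members by `contains`
edges; the anchored interaction is split in two at the connector node
`anch0`; and the interaction between the two copies of gene 1000 becomes
a self-loop on the merged node. Overlaying generated expression data:

```python
data, mapping = make_demo_data(doc, seed=1)   # logFC ~ N(0, 1.5), BH-adjusted p
map_identifiers(graph, mapping)
join_data(graph, data)
overlay = apply_data_styles(graph)
print(graph.meta["measured_count"], "measured;",
      graph.meta["mapping_report"]["unmapped"], "unmapped")
```

prints `3 measured; 1 unmapped` — three molecules get gradient fills and
the unmapped one is styled grey.

The same workflow from the shell:

```
pathwayviews convert  pathway.gpml --view network --format sif --out net.sif
pathwayviews overlay  pathway.gpml --data data.tsv --mapping map.tsv \
                      --format json --out overlay.json
pathwayviews fetch    WP2795 --out WP2795.gpml        # cancellable with Ctrl-C
```

Exit codes: 0 success, 2 unreadable/unparseable input, 3 pathway not
found, 64 bad flags, 130 cancelled.

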
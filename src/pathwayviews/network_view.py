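"""Simplified molecule-interaction network view.

The network view strips everything decorative from the diagram and
keeps only biology: labels, shapes and graphical lines vanish; data
nodes that reference the same biological entity collapse into a single
node; groups and interaction anchors survive as very small connector
nodes so complex wiring (a catalysis edge touching a conversion edge)
stays structurally intact.  A seeded force-directed layout replaces the
drawn coordinates, making the whole conversion reproducible.

Redundancy is decided by cross-reference identity: two data nodes
annotated with the same (datasource, identifier) pair are the same
entity no matter where they are drawn.  Nodes without a usable
cross-reference fall back to (entity type, text label) equality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import networkx as nx

from .graph import DeferredStyle, NetworkGraph, StyleTable, apply_styles, record_style
from .model import DataNode, PathwayDocument, require_valid
from .pathway_view import group_node_id

logger = logging.getLogger(__name__)

__all__ = [
    "MergeKey",
    "NetworkOptions",
    "merge_key",
    "merge_report",
    "to_network_view",
    "apply_layout",
]

#: width/height (board units) of group and connector nodes in the view
SMALL_NODE_SIZE = 5.0


@dataclass(frozen=True)
class MergeKey:
    """Identity under which data nodes merge.

    ``kind`` is ``"xref"`` (datasource + identifier) or ``"label"``
    (entity_type + case-sensitive text label, the fallback for nodes
    without a complete cross-reference).
    """

    kind: str
    first: str
    second: str

    def __str__(self) -> str:
        return f"{self.kind}:{self.first}:{self.second}"


@dataclass
class NetworkOptions:
    """Tunables of the network conversion."""

    collapse_parallel_edges: bool = True
    drop_dangling_edges: bool = True
    layout_seed: int = 42
    layout_iterations: int = 100

    def __post_init__(self) -> None:
        if self.layout_iterations < 1:
            raise ValueError("layout_iterations must be >= 1")


def merge_key(node: DataNode) -> MergeKey:
    """The merge identity of one data node (xref first, label fallback)."""
    if not node.xref.is_empty():
        return MergeKey("xref", node.xref.datasource, node.xref.identifier)
    return MergeKey("label", node.entity_type, node.text_label)


def merge_report(doc: PathwayDocument) -> dict[MergeKey, list[str]]:
    """MergeKey -> graph_ids of the data nodes it absorbs (document order).

    The lists partition the full set of DataNode ids.
    """
    report: dict[MergeKey, list[str]] = {}
    for dn in doc.data_nodes:
        report.setdefault(merge_key(dn), []).append(dn.graph_id)
    return report


def apply_layout(
    graph: NetworkGraph, seed: int = 42, iterations: int = 100
) -> dict[str, tuple[float, float]]:
    """Seeded Fruchterman–Reingold coordinates for every node.

    Deterministic for a fixed (graph, seed, iterations); a single node
    is placed at the origin.  Raises ValueError on an empty graph.
    """
    if not graph.nodes:
        raise ValueError("cannot lay out an empty graph")
    if len(graph.nodes) == 1:
        (nid,) = graph.nodes
        return {nid: (0.0, 0.0)}
    g = graph.to_networkx(simple_undirected=True)
    pos = nx.spring_layout(g, seed=seed, iterations=iterations)
    coords = {nid: (float(p[0]), float(p[1])) for nid, p in pos.items()}
    return {nid: coords[nid] for nid in sorted(coords)}


def to_network_view(
    doc: PathwayDocument, opts: Optional[NetworkOptions] = None
) -> tuple[NetworkGraph, StyleTable]:
    """Convert a valid document into the simplified network view.

    Molecule nodes are in bijection with distinct merge keys; each
    group becomes one small node joined to its members by undirected
    ``contains`` edges; each anchor becomes one small connector node
    splitting its interaction's edge.  Positions come from the seeded
    force-directed layout, so the result is fully reproducible from
    (document, options).
    """
    require_valid(doc)
    opts = opts or NetworkOptions()
    graph = NetworkGraph()
    buf: list[DeferredStyle] = []

    # --- merge data nodes -------------------------------------------------
    report = merge_report(doc)
    by_id = {dn.graph_id: dn for dn in doc.data_nodes}
    node_for: dict[str, str] = {}  # datanode graph_id -> merged node id
    for key, gids in report.items():
        rep = by_id[gids[0]]  # representative: first in document order
        graph.add_node(
            rep.graph_id,
            "molecule",
            label=rep.text_label,
            entity_type=rep.entity_type,
            xref_datasource=rep.xref.datasource,
            xref_identifier=rep.xref.identifier,
            merge_key=str(key),
            merged_ids=";".join(gids),
            merged_count=len(gids),
        )
        record_style(buf, rep.graph_id, "width", rep.graphics.width)
        record_style(buf, rep.graph_id, "height", rep.graphics.height)
        record_style(buf, rep.graph_id, "fill_color", rep.graphics.fill_color)
        record_style(buf, rep.graph_id, "border_color", rep.graphics.border_color)
        record_style(buf, rep.graph_id, "shape", rep.graphics.shape_name)
        record_style(buf, rep.graph_id, "label", rep.text_label)
        for gid in gids:
            node_for[gid] = rep.graph_id
    graph.meta["merged_node_count"] = sum(1 for gids in report.values() if len(gids) > 1)
    graph.meta["datanode_count"] = len(doc.data_nodes)

    def small_node_styles(nid: str) -> None:
        record_style(buf, nid, "width", SMALL_NODE_SIZE)
        record_style(buf, nid, "height", SMALL_NODE_SIZE)
        record_style(buf, nid, "fill_color", "808080")
        record_style(buf, nid, "border_color", "000000")
        record_style(buf, nid, "shape", "Ellipse")

    # --- groups as small nodes with "contains" edges ----------------------
    for g in doc.groups:
        nid = group_node_id(g)
        graph.add_node(nid, "group", label=g.group_id, group_style=g.style)
        small_node_styles(nid)
        for member in doc.group_members(g):
            if isinstance(member, DataNode):
                target = node_for[member.graph_id]
                eid = f"contains:{g.group_id}:{member.graph_id}"
                graph.add_edge(eid, nid, target, interaction_type="contains", directed=False)

    # --- anchors on biologically used interactions ------------------------
    for ia in doc.interactions:
        for a in ia.anchors:
            graph.add_node(a.graph_id, "connector", label="", parent_line=ia.graph_id)
            small_node_styles(a.graph_id)

    # --- interaction edges (graphical lines contribute nothing) ----------
    endpoints: dict[str, str] = dict(node_for)
    for g in doc.groups:
        gid = group_node_id(g)
        endpoints[g.group_id] = gid
        if g.graph_id is not None:
            endpoints[g.graph_id] = gid
    for ia in doc.interactions:
        for a in ia.anchors:
            endpoints[a.graph_id] = a.graph_id

    dropped = 0
    for ia in doc.interactions:
        src_ref = ia.points[0].graph_ref
        tgt_ref = ia.points[-1].graph_ref
        arrow = ia.points[-1].arrow_head
        itype = arrow if arrow else "undirected"
        directed = arrow is not None
        src = endpoints.get(src_ref) if src_ref else None
        tgt = endpoints.get(tgt_ref) if tgt_ref else None

        if src is None and tgt is None and not ia.anchors:
            logger.warning("interaction %s dropped entirely (both endpoints dangling)", ia.graph_id)
            dropped += 1
            continue

        stops: list[Optional[str]] = [src]
        stops += [a.graph_id for a in sorted(ia.anchors, key=lambda a: a.position)]
        stops.append(tgt)
        n_emitted = 0
        for i in range(len(stops) - 1):
            a, b = stops[i], stops[i + 1]
            if a is None or b is None:
                if opts.drop_dangling_edges:
                    logger.warning("interaction %s: dangling segment dropped", ia.graph_id)
                    dropped += 1
                    continue
                # keep structure: a placeholder connector stands in for
                # the missing endpoint
                ph = f"dangling:{ia.graph_id}:{i}"
                if ph not in graph.nodes:
                    graph.add_node(ph, "connector", label="", placeholder=True)
                    small_node_styles(ph)
                a = a or ph
                b = b or ph
            eid = f"{ia.graph_id}.{n_emitted}" if len(stops) > 2 else ia.graph_id
            graph.add_edge(eid, a, b, interaction_type=itype, directed=directed, parent_line=ia.graph_id)
            n_emitted += 1
    graph.meta["dropped_dangling_edges"] = dropped

    if opts.collapse_parallel_edges:
        _collapse_parallel(graph)

    # --- seeded force-directed layout ------------------------------------
    if graph.nodes:
        coords = apply_layout(graph, seed=opts.layout_seed, iterations=opts.layout_iterations)
        for nid, (x, y) in coords.items():
            record_style(buf, nid, "x", x)
            record_style(buf, nid, "y", y)

    return graph, apply_styles(graph, buf)


def _collapse_parallel(graph: NetworkGraph) -> None:
    """Collapse edges sharing (source, target, interaction_type) into one
    edge carrying a ``multiplicity`` attribute (undirected edges compare
    with sorted endpoints)."""
    seen: dict[tuple, str] = {}
    for eid in sorted(graph.edges):
        e = graph.edges[eid]
        ends = (e.source, e.target) if e.directed else tuple(sorted((e.source, e.target)))
        key = (ends, e.interaction_type, e.directed)
        if key in seen:
            kept = graph.edges[seen[key]]
            kept.attributes["multiplicity"] = kept.attributes.get("multiplicity", 1) + 1
            del graph.edges[eid]
        else:
            e.attributes.setdefault("multiplicity", 1)
            seen[key] = eid
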
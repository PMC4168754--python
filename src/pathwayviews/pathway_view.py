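"""Annotated pathway view: a graph that replicates the drawn diagram.

Every diagram element survives: data nodes become ``molecule`` nodes,
labels and shapes become ``annotation`` nodes, groups become ``group``
nodes and interaction anchors become ``connector`` nodes.  Node
positions in the style table equal the GPML center coordinates exactly
— the layout of the view is the layout of the diagram.

Decorative graphical lines are kept as undirected edges flagged
``graphical=True`` so the view loses nothing the curator drew.
"""

from __future__ import annotations

import logging
from typing import Optional, Union

from .graph import DeferredStyle, NetworkGraph, StyleTable, apply_styles, record_style
from .model import (
    GraphicalLine,
    Group,
    Interaction,
    PathwayDocument,
    require_valid,
)

logger = logging.getLogger(__name__)

__all__ = ["to_pathway_view", "group_node_id", "record_style", "apply_styles"]


def group_node_id(group: Group) -> str:
    """Stable node id for a group (GraphId when present, else group:<id>)."""
    return group.graph_id if group.graph_id is not None else f"group:{group.group_id}"


def _endpoint_map(doc: PathwayDocument) -> dict[str, str]:
    """graph_ref -> node id for everything that can terminate an edge."""
    m: dict[str, str] = {}
    for dn in doc.data_nodes:
        m[dn.graph_id] = dn.graph_id
    for lab in doc.labels:
        m[lab.graph_id] = lab.graph_id
    for sh in doc.shapes:
        m[sh.graph_id] = sh.graph_id
    for _, a in doc.iter_anchors():
        m[a.graph_id] = a.graph_id
    for g in doc.groups:
        gid = group_node_id(g)
        m[group_node_id(g)] = gid
        m[g.group_id] = gid
        if g.graph_id is not None:
            m[g.graph_id] = gid
    return m


def _group_bbox_center(doc: PathwayDocument, group: Group) -> tuple[float, float, float, float]:
    """Bounding-box center and size of a group's members (cx, cy, w, h).

    GPML stores no coordinates for groups; an empty group sits at the
    origin with a minimal box.
    """
    members = doc.group_members(group)
    if not members:
        return 0.0, 0.0, 5.0, 5.0
    xs0 = [m.graphics.center_x - m.graphics.width / 2 for m in members]
    xs1 = [m.graphics.center_x + m.graphics.width / 2 for m in members]
    ys0 = [m.graphics.center_y - m.graphics.height / 2 for m in members]
    ys1 = [m.graphics.center_y + m.graphics.height / 2 for m in members]
    x0, x1, y0, y1 = min(xs0), max(xs1), min(ys0), max(ys1)
    return (x0 + x1) / 2, (y0 + y1) / 2, x1 - x0, y1 - y0


def _line_edges(
    graph: NetworkGraph,
    buf: list[DeferredStyle],
    line: Union[Interaction, GraphicalLine],
    endpoints: dict[str, str],
    *,
    graphical: bool,
) -> None:
    """Add the edge chain for one interaction/graphical line.

    The line runs source -> [anchor...] -> target, splitting at its own
    anchors (sorted by position).  Endpoints that resolve to nothing
    drop their segment with a warning; the connector nodes stay.
    """
    src_ref = line.points[0].graph_ref
    tgt_ref = line.points[-1].graph_ref
    arrow = line.points[-1].arrow_head
    itype = "graphical" if graphical else (arrow if arrow else "undirected")
    directed = (not graphical) and arrow is not None

    src = endpoints.get(src_ref) if src_ref else None
    tgt = endpoints.get(tgt_ref) if tgt_ref else None
    if src_ref and src is None:
        logger.warning("%s: source ref %r unresolvable", line.graph_id, src_ref)
    if tgt_ref and tgt is None:
        logger.warning("%s: target ref %r unresolvable", line.graph_id, tgt_ref)

    stops: list[Optional[str]] = [src]
    stops += [a.graph_id for a in sorted(line.anchors, key=lambda a: a.position)]
    stops.append(tgt)

    n_emitted = 0
    for i in range(len(stops) - 1):
        a, b = stops[i], stops[i + 1]
        if a is None or b is None:
            logger.warning("%s: segment %d dropped (dangling endpoint)", line.graph_id, i)
            continue
        eid = f"{line.graph_id}.{n_emitted}" if len(stops) > 2 else line.graph_id
        last = i == len(stops) - 2
        graph.add_edge(
            eid,
            a,
            b,
            interaction_type=itype,
            directed=directed,
            graphical=graphical,
            parent_line=line.graph_id,
        )
        record_style(buf, eid, "line_style", line.graphics.line_style)
        record_style(buf, eid, "arrow_shape", (arrow or "none") if (last and not graphical) else "none")
        n_emitted += 1


def to_pathway_view(doc: PathwayDocument) -> tuple[NetworkGraph, StyleTable]:
    """Convert a valid document into the pathway view and its styles.

    Raises InvalidDocumentError on a document with validation errors.
    Guarantees: node count equals |DataNodes| + |Labels| + |Shapes| +
    |Groups| + |Anchors|; every node carries exact x/y (diagram
    coordinates), width/height and colors in the style table.
    """
    require_valid(doc)
    graph = NetworkGraph()
    buf: list[DeferredStyle] = []

    def record_box(nid: str, gp, label: Optional[str] = None) -> None:
        record_style(buf, nid, "x", gp.center_x)
        record_style(buf, nid, "y", gp.center_y)
        record_style(buf, nid, "width", gp.width)
        record_style(buf, nid, "height", gp.height)
        record_style(buf, nid, "fill_color", gp.fill_color)
        record_style(buf, nid, "border_color", gp.border_color)
        record_style(buf, nid, "shape", gp.shape_name)
        record_style(buf, nid, "z_order", gp.z_order)
        if label is not None:
            record_style(buf, nid, "label", label)

    for dn in doc.data_nodes:
        graph.add_node(
            dn.graph_id,
            "molecule",
            label=dn.text_label,
            entity_type=dn.entity_type,
            xref_datasource=dn.xref.datasource,
            xref_identifier=dn.xref.identifier,
            states=";".join(st.text_label for st in dn.states),
        )
        record_box(dn.graph_id, dn.graphics, dn.text_label)
    for lab in doc.labels:
        graph.add_node(lab.graph_id, "annotation", label=lab.text_label, element="Label")
        record_box(lab.graph_id, lab.graphics, lab.text_label)
    for sh in doc.shapes:
        graph.add_node(sh.graph_id, "annotation", label="", element="Shape")
        record_box(sh.graph_id, sh.graphics)

    for g in doc.groups:
        nid = group_node_id(g)
        graph.add_node(nid, "group", label=g.group_id, group_style=g.style)
        cx, cy, w, h = _group_bbox_center(doc, g)
        record_style(buf, nid, "x", cx)
        record_style(buf, nid, "y", cy)
        record_style(buf, nid, "width", w)
        record_style(buf, nid, "height", h)
        record_style(buf, nid, "fill_color", "FFFFFF")
        record_style(buf, nid, "border_color", "808080")
        record_style(buf, nid, "shape", "Rectangle")
        record_style(buf, nid, "z_order", -1)

    # anchors: connector nodes at the interpolated coordinate along the
    # straight source->target segment of their parent line
    for line, anchor in doc.iter_anchors():
        p0, p1 = line.points[0], line.points[-1]
        ax = p0.x + (p1.x - p0.x) * anchor.position
        ay = p0.y + (p1.y - p0.y) * anchor.position
        graph.add_node(anchor.graph_id, "connector", label="", parent_line=line.graph_id)
        record_style(buf, anchor.graph_id, "x", ax)
        record_style(buf, anchor.graph_id, "y", ay)
        record_style(buf, anchor.graph_id, "width", 5.0)
        record_style(buf, anchor.graph_id, "height", 5.0)
        record_style(buf, anchor.graph_id, "fill_color", "000000")
        record_style(buf, anchor.graph_id, "border_color", "000000")
        record_style(buf, anchor.graph_id, "shape", "Ellipse")
        record_style(buf, anchor.graph_id, "z_order", 0)

    endpoints = _endpoint_map(doc)
    for ia in doc.interactions:
        _line_edges(graph, buf, ia, endpoints, graphical=False)
    for gl in doc.graphical_lines:
        _line_edges(graph, buf, gl, endpoints, graphical=True)

    return graph, apply_styles(graph, buf)
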
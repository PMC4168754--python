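"""Read and write GPML 2013a XML.

Only the 2013a namespace (``http://pathvisio.org/GPML/2013a``) is
supported; documents in older or newer namespaces are rejected with an
unsupported-format error rather than mis-parsed.

Attributes the file omits take fixed defaults (fill ``FFFFFF``, border
``000000``, z-order 0, solid lines) so downstream styling is
deterministic.  Unknown elements (Biopax, InfoBox, Legend, ...) are
skipped with a logged warning, never an error.  Elements that are
referenced elsewhere but carry no GraphId of their own receive synthetic
ids ``auto:<n>``.
"""

from __future__ import annotations

import logging
from typing import Optional, Union

from lxml import etree

from .model import (
    Anchor,
    DataNode,
    GraphicalLine,
    GraphicsProps,
    Group,
    Interaction,
    Label,
    PathwayDocument,
    Point,
    Shape,
    State,
    Xref,
    ENTITY_TYPES,
    GROUP_STYLES,
    normalize_color,
    require_valid,
)

logger = logging.getLogger(__name__)

GPML_2013A_NS = "http://pathvisio.org/GPML/2013a"
_NS = "{%s}" % GPML_2013A_NS

__all__ = ["parse_gpml", "write_gpml", "GpmlParseError", "UnsupportedFormatError", "GPML_2013A_NS"]


class GpmlParseError(ValueError):
    """Malformed XML or GPML structure; carries a line number when known."""


class UnsupportedFormatError(ValueError):
    """The document is XML but not GPML 2013a."""


def _localname(el: etree._Element) -> str:
    return etree.QName(el).localname


def _float(attrs, key: str, default: float = 0.0) -> float:
    raw = attrs.get(key)
    return default if raw is None else float(raw)


def _color(attrs, key: str, default: str) -> str:
    raw = attrs.get(key)
    if raw is None:
        return default
    try:
        return normalize_color(raw)
    except ValueError:
        logger.warning("unrecognized color %r for %s; using default %s", raw, key, default)
        return default


class _IdGen:
    """Synthetic ids for elements the file left unidentified."""

    def __init__(self) -> None:
        self.n = 0

    def __call__(self, el_kind: str) -> str:
        self.n += 1
        gid = f"auto:{self.n}"
        logger.warning("%s without GraphId; assigned synthetic id %s", el_kind, gid)
        return gid


def _parse_graphics(parent: etree._Element) -> GraphicsProps:
    gp = GraphicsProps()
    g = parent.find(_NS + "Graphics")
    if g is None:
        return gp
    a = g.attrib
    gp.center_x = _float(a, "CenterX")
    gp.center_y = _float(a, "CenterY")
    gp.width = _float(a, "Width", 1.0)
    gp.height = _float(a, "Height", 1.0)
    gp.fill_color = _color(a, "FillColor", "FFFFFF")
    gp.border_color = _color(a, "Color", "000000")
    gp.shape_name = a.get("ShapeType", "Rectangle")
    gp.z_order = int(a.get("ZOrder", "0"))
    gp.line_style = "dashed" if a.get("LineStyle") == "Broken" else "solid"
    gp.line_thickness = _float(a, "LineThickness", 1.0)
    return gp


def _parse_xref(parent: etree._Element) -> Xref:
    x = parent.find(_NS + "Xref")
    if x is None:
        return Xref()
    return Xref(
        datasource=(x.get("Database") or "").strip(),
        identifier=(x.get("ID") or "").strip(),
    )


def _parse_line_body(
    el: etree._Element, gid: str, idgen: _IdGen
) -> tuple[list[Point], list[Anchor], GraphicsProps]:
    points: list[Point] = []
    anchors: list[Anchor] = []
    gp = GraphicsProps()
    g = el.find(_NS + "Graphics")
    if g is not None:
        a = g.attrib
        gp.border_color = _color(a, "Color", "000000")
        gp.z_order = int(a.get("ZOrder", "0"))
        gp.line_style = "dashed" if a.get("LineStyle") == "Broken" else "solid"
        gp.line_thickness = _float(a, "LineThickness", 1.0)
        for child in g:
            name = _localname(child)
            if name == "Point":
                arrow = child.get("ArrowHead")
                points.append(
                    Point(
                        x=_float(child.attrib, "X"),
                        y=_float(child.attrib, "Y"),
                        graph_ref=child.get("GraphRef"),
                        arrow_head=arrow,
                    )
                )
            elif name == "Anchor":
                anchors.append(
                    Anchor(
                        graph_id=child.get("GraphId") or idgen("Anchor"),
                        position=_float(child.attrib, "Position", 0.5),
                        shape=child.get("Shape", "None"),
                    )
                )
    return points, anchors, gp


def parse_gpml(xml_text: Union[str, bytes]) -> PathwayDocument:
    """Parse GPML 2013a text into a PathwayDocument.

    Raises GpmlParseError on malformed XML (message includes the line
    number) and UnsupportedFormatError when the root element is not a
    2013a ``Pathway``.  Unknown child elements are skipped with a
    warning; element document order is preserved.
    """
    data = xml_text.encode("utf-8") if isinstance(xml_text, str) else xml_text
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as e:
        line = e.lineno if e.lineno else "?"
        raise GpmlParseError(f"malformed XML at line {line}: {e.msg}") from e

    qname = etree.QName(root)
    if qname.localname != "Pathway":
        raise UnsupportedFormatError(f"root element is <{qname.localname}>, expected <Pathway>")
    if qname.namespace != GPML_2013A_NS:
        raise UnsupportedFormatError(
            f"unsupported GPML namespace {qname.namespace!r}; only 2013a "
            f"({GPML_2013A_NS!r}) is supported"
        )

    doc = PathwayDocument(
        name=root.get("Name", ""),
        organism=root.get("Organism", ""),
        gpml_version="2013a",
    )
    idgen = _IdGen()
    pending_states: list[State] = []

    for el in root:
        if not isinstance(el.tag, str):  # comments / PIs
            continue
        name = _localname(el)
        if name == "Graphics":
            doc.board_width = _float(el.attrib, "BoardWidth")
            doc.board_height = _float(el.attrib, "BoardHeight")
        elif name == "DataNode":
            etype = el.get("Type", "Unknown")
            if etype not in ENTITY_TYPES:
                logger.warning("unknown DataNode type %r; treating as Unknown", etype)
                etype = "Unknown"
            doc.data_nodes.append(
                DataNode(
                    graph_id=el.get("GraphId") or idgen("DataNode"),
                    text_label=el.get("TextLabel", ""),
                    entity_type=etype,
                    xref=_parse_xref(el),
                    group_ref=el.get("GroupRef"),
                    graphics=_parse_graphics(el),
                )
            )
        elif name == "State":
            ref = el.get("GraphRef")
            if ref is None:
                logger.warning("State without GraphRef skipped")
                continue
            pending_states.append(
                State(
                    graph_ref=ref,
                    text_label=el.get("TextLabel", ""),
                    rel_x=_float(el.attrib, "RelX"),
                    rel_y=_float(el.attrib, "RelY"),
                )
            )
        elif name == "Interaction":
            gid = el.get("GraphId") or idgen("Interaction")
            points, anchors, gp = _parse_line_body(el, gid, idgen)
            doc.interactions.append(
                Interaction(
                    graph_id=gid,
                    points=points,
                    anchors=anchors,
                    xref=_parse_xref(el),
                    group_ref=el.get("GroupRef"),
                    graphics=gp,
                )
            )
        elif name == "GraphicalLine":
            gid = el.get("GraphId") or idgen("GraphicalLine")
            points, anchors, gp = _parse_line_body(el, gid, idgen)
            doc.graphical_lines.append(
                GraphicalLine(graph_id=gid, points=points, anchors=anchors, graphics=gp)
            )
        elif name == "Label":
            doc.labels.append(
                Label(
                    graph_id=el.get("GraphId") or idgen("Label"),
                    text_label=el.get("TextLabel", ""),
                    graphics=_parse_graphics(el),
                    group_ref=el.get("GroupRef"),
                )
            )
        elif name == "Shape":
            doc.shapes.append(
                Shape(
                    graph_id=el.get("GraphId") or idgen("Shape"),
                    graphics=_parse_graphics(el),
                    group_ref=el.get("GroupRef"),
                )
            )
        elif name == "Group":
            gid = el.get("GroupId")
            if gid is None:
                logger.warning("Group without GroupId skipped")
                continue
            style = el.get("Style", "Group")
            if style not in GROUP_STYLES:
                logger.warning("unknown group style %r; treating as Group", style)
                style = "Group"
            doc.groups.append(Group(group_id=gid, graph_id=el.get("GraphId"), style=style))
        else:
            logger.warning("skipping unsupported GPML element <%s>", name)

    by_id = {dn.graph_id: dn for dn in doc.data_nodes}
    for st in pending_states:
        parent = by_id.get(st.graph_ref)
        if parent is None:
            logger.warning("State refers to unknown DataNode %r; dropped", st.graph_ref)
        else:
            parent.states.append(st)
    return doc


def _fmt(x: float) -> str:
    # shortest representation that round-trips through float()
    return repr(float(x))


def _graphics_attrs(gp: GraphicsProps, *, line: bool) -> dict[str, str]:
    attrs: dict[str, str] = {}
    if not line:
        attrs["CenterX"] = _fmt(gp.center_x)
        attrs["CenterY"] = _fmt(gp.center_y)
        attrs["Width"] = _fmt(gp.width)
        attrs["Height"] = _fmt(gp.height)
        attrs["FillColor"] = gp.fill_color
        attrs["ShapeType"] = gp.shape_name
    attrs["Color"] = gp.border_color
    attrs["ZOrder"] = str(gp.z_order)
    if gp.line_style == "dashed":
        attrs["LineStyle"] = "Broken"
    attrs["LineThickness"] = _fmt(gp.line_thickness)
    return attrs


def write_gpml(doc: PathwayDocument) -> str:
    """Serialize a document back to GPML 2013a text.

    Refuses (InvalidDocumentError, citing the first issue) when the
    document fails validation.  Output re-parses to a structurally
    equal model.
    """
    require_valid(doc)
    nsmap = {None: GPML_2013A_NS}
    root = etree.Element(_NS + "Pathway", nsmap=nsmap)
    root.set("Name", doc.name)
    root.set("Organism", doc.organism)
    root.set("Version", doc.gpml_version)
    etree.SubElement(
        root,
        _NS + "Graphics",
        BoardWidth=_fmt(doc.board_width),
        BoardHeight=_fmt(doc.board_height),
    )

    def emit_xref(parent: etree._Element, xref: Xref) -> None:
        etree.SubElement(parent, _NS + "Xref", Database=xref.datasource, ID=xref.identifier)

    for dn in doc.data_nodes:
        el = etree.SubElement(root, _NS + "DataNode")
        el.set("TextLabel", dn.text_label)
        el.set("GraphId", dn.graph_id)
        el.set("Type", dn.entity_type)
        if dn.group_ref is not None:
            el.set("GroupRef", dn.group_ref)
        etree.SubElement(el, _NS + "Graphics", **_graphics_attrs(dn.graphics, line=False))
        emit_xref(el, dn.xref)
    for dn in doc.data_nodes:
        for st in dn.states:
            el = etree.SubElement(root, _NS + "State")
            el.set("GraphRef", st.graph_ref)
            el.set("TextLabel", st.text_label)
            el.set("RelX", _fmt(st.rel_x))
            el.set("RelY", _fmt(st.rel_y))

    def emit_line(tag: str, line: Union[Interaction, GraphicalLine]) -> etree._Element:
        el = etree.SubElement(root, _NS + tag)
        el.set("GraphId", line.graph_id)
        if isinstance(line, Interaction) and line.group_ref is not None:
            el.set("GroupRef", line.group_ref)
        g = etree.SubElement(el, _NS + "Graphics", **_graphics_attrs(line.graphics, line=True))
        for p in line.points:
            pel = etree.SubElement(g, _NS + "Point", X=_fmt(p.x), Y=_fmt(p.y))
            if p.graph_ref is not None:
                pel.set("GraphRef", p.graph_ref)
            if p.arrow_head is not None:
                pel.set("ArrowHead", p.arrow_head)
        for a in line.anchors:
            etree.SubElement(
                g, _NS + "Anchor", Position=_fmt(a.position), GraphId=a.graph_id, Shape=a.shape
            )
        return el

    for ia in doc.interactions:
        el = emit_line("Interaction", ia)
        emit_xref(el, ia.xref)
    for gl in doc.graphical_lines:
        emit_line("GraphicalLine", gl)
    for lab in doc.labels:
        el = etree.SubElement(root, _NS + "Label")
        el.set("TextLabel", lab.text_label)
        el.set("GraphId", lab.graph_id)
        if lab.group_ref is not None:
            el.set("GroupRef", lab.group_ref)
        etree.SubElement(el, _NS + "Graphics", **_graphics_attrs(lab.graphics, line=False))
    for sh in doc.shapes:
        el = etree.SubElement(root, _NS + "Shape")
        el.set("GraphId", sh.graph_id)
        if sh.group_ref is not None:
            el.set("GroupRef", sh.group_ref)
        etree.SubElement(el, _NS + "Graphics", **_graphics_attrs(sh.graphics, line=False))
    for g in doc.groups:
        el = etree.SubElement(root, _NS + "Group", GroupId=g.group_id, Style=g.style)
        if g.graph_id is not None:
            el.set("GraphId", g.graph_id)

    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    ).decode("utf-8")
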
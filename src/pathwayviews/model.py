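"""Typed in-memory model of a GPML 2013a pathway.

GPML (Graphical Pathway Markup Language) is the XML dialect in which
WikiPathways stores pathway diagrams.  The model here covers the subset
the two view converters consume: data nodes (biological entities with a
cross-reference), interactions with anchor points, groups/complexes,
free-text labels, decorative shapes, and modification states.

Coordinates are kept in native board units with the origin at the top
left and y growing downward, exactly as drawn at WikiPathways; no
rescaling is ever applied.  Colors are normalized to uppercase ``RRGGBB``
hex strings.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Optional, Union

__all__ = [
    "Xref",
    "GraphicsProps",
    "State",
    "DataNode",
    "Anchor",
    "Point",
    "Interaction",
    "GraphicalLine",
    "Label",
    "Shape",
    "Group",
    "PathwayDocument",
    "Issue",
    "validate",
    "resolve",
    "normalize_color",
    "InvalidDocumentError",
]

_HEX_COLOR = re.compile(r"^[0-9A-F]{6}$")

#: Fixed mapping of GPML named colors to RRGGBB hex.
NAMED_COLORS = {
    "Black": "000000",
    "White": "FFFFFF",
    "Red": "FF0000",
    "Green": "00FF00",
    "Blue": "0000FF",
    "Yellow": "FFFF00",
    "Orange": "FFA500",
    "Gray": "808080",
    "Grey": "808080",
    "LightGray": "D3D3D3",
    "DarkGray": "A9A9A9",
    "Cyan": "00FFFF",
    "Magenta": "FF00FF",
    "Purple": "800080",
    "Brown": "A52A2A",
    "Pink": "FFC0CB",
    "Transparent": "FFFFFF",
}

ENTITY_TYPES = ("GeneProduct", "Protein", "Rna", "Metabolite", "Pathway", "Unknown")
GROUP_STYLES = ("Group", "Complex", "Pathway", "None")
LINE_STYLES = ("solid", "dashed")


class InvalidDocumentError(ValueError):
    """Raised when an operation requires a document free of validation errors."""


def normalize_color(value: str) -> str:
    """Normalize a GPML color string to uppercase RRGGBB hex.

    Accepts 6-digit hex (with or without a leading ``#``), 8-digit
    ARGB hex (alpha stripped), and the fixed table of named colors.
    """
    v = value.strip().lstrip("#")
    if v in NAMED_COLORS:
        return NAMED_COLORS[v]
    v = v.upper()
    if len(v) == 8 and re.fullmatch(r"[0-9A-F]{8}", v):
        v = v[2:]  # ARGB -> RGB
    if _HEX_COLOR.match(v):
        return v
    raise ValueError(f"unrecognized color {value!r}")


@dataclass(frozen=True)
class Xref:
    """Cross-reference annotating an entity, e.g. Entrez Gene 1017."""

    datasource: str = ""
    identifier: str = ""

    def is_empty(self) -> bool:
        return not (self.datasource and self.identifier)


@dataclass
class GraphicsProps:
    """Drawing properties of one diagram element (board units, y-down)."""

    center_x: float = 0.0
    center_y: float = 0.0
    width: float = 1.0
    height: float = 1.0
    fill_color: str = "FFFFFF"
    border_color: str = "000000"
    shape_name: str = "Rectangle"
    z_order: int = 0
    line_style: str = "solid"
    line_thickness: float = 1.0


@dataclass
class State:
    """Modification state pinned to a parent data node.

    ``rel_x``/``rel_y`` place the state on the parent's bounding box as
    fractions in [-1, 1].  States never become graph nodes; they travel
    as attributes of their parent.
    """

    graph_ref: str
    text_label: str = ""
    rel_x: float = 0.0
    rel_y: float = 0.0


@dataclass
class DataNode:
    """A biological entity drawn in the pathway (gene product, metabolite, ...)."""

    graph_id: str
    text_label: str = ""
    entity_type: str = "Unknown"
    xref: Xref = field(default_factory=Xref)
    group_ref: Optional[str] = None
    graphics: GraphicsProps = field(default_factory=GraphicsProps)
    states: list[State] = field(default_factory=list)


@dataclass
class Anchor:
    """A point on an interaction line where another interaction attaches."""

    graph_id: str
    position: float = 0.5
    shape: str = "None"


@dataclass
class Point:
    """One endpoint or waypoint of an interaction line."""

    x: float = 0.0
    y: float = 0.0
    graph_ref: Optional[str] = None
    arrow_head: Optional[str] = None


@dataclass
class Interaction:
    """A biological interaction; first and last point are source and target."""

    graph_id: str
    points: list[Point] = field(default_factory=list)
    anchors: list[Anchor] = field(default_factory=list)
    xref: Xref = field(default_factory=Xref)
    group_ref: Optional[str] = None
    graphics: GraphicsProps = field(default_factory=GraphicsProps)


@dataclass
class GraphicalLine:
    """A decorative line with no biological meaning; never a network edge."""

    graph_id: str
    points: list[Point] = field(default_factory=list)
    anchors: list[Anchor] = field(default_factory=list)
    graphics: GraphicsProps = field(default_factory=GraphicsProps)


@dataclass
class Label:
    """Free-text annotation drawn on the board."""

    graph_id: str
    text_label: str = ""
    graphics: GraphicsProps = field(default_factory=GraphicsProps)
    group_ref: Optional[str] = None


@dataclass
class Shape:
    """Decorative shape (box, oval, cell compartment outline, ...)."""

    graph_id: str
    graphics: GraphicsProps = field(default_factory=GraphicsProps)
    group_ref: Optional[str] = None


@dataclass
class Group:
    """Container of elements whose ``group_ref`` names this group."""

    group_id: str
    graph_id: Optional[str] = None
    style: str = "Group"


Element = Union[DataNode, Interaction, GraphicalLine, Label, Shape, Group, Anchor]


@dataclass
class PathwayDocument:
    """One parsed GPML pathway with all element collections."""

    name: str = ""
    organism: str = ""
    gpml_version: str = "2013a"
    board_width: float = 0.0
    board_height: float = 0.0
    data_nodes: list[DataNode] = field(default_factory=list)
    interactions: list[Interaction] = field(default_factory=list)
    graphical_lines: list[GraphicalLine] = field(default_factory=list)
    labels: list[Label] = field(default_factory=list)
    shapes: list[Shape] = field(default_factory=list)
    groups: list[Group] = field(default_factory=list)

    def iter_anchors(self) -> Iterator[tuple[Union[Interaction, GraphicalLine], Anchor]]:
        for line in [*self.interactions, *self.graphical_lines]:
            for a in line.anchors:
                yield line, a

    def group_members(self, group: Group) -> list[Union[DataNode, Label, Shape]]:
        """Elements whose group_ref equals the group's id, in document order."""
        out: list[Union[DataNode, Label, Shape]] = []
        for el in [*self.data_nodes, *self.labels, *self.shapes]:
            if el.group_ref == group.group_id:
                out.append(el)
        return out


@dataclass(frozen=True)
class Issue:
    """One validation finding; ``severity`` is 'error' or 'warning'."""

    severity: str
    element_id: str
    message: str


def _ref_index(doc: PathwayDocument) -> dict[str, Element]:
    """Index of every graph_id (and Group group_id) to its element.

    Duplicates keep the first occurrence; validate() reports them.
    """
    idx: dict[str, Element] = {}

    def put(key: Optional[str], el: Element) -> None:
        if key and key not in idx:
            idx[key] = el

    for dn in doc.data_nodes:
        put(dn.graph_id, dn)
    for lab in doc.labels:
        put(lab.graph_id, lab)
    for sh in doc.shapes:
        put(sh.graph_id, sh)
    for ia in doc.interactions:
        put(ia.graph_id, ia)
    for gl in doc.graphical_lines:
        put(gl.graph_id, gl)
    for _, a in doc.iter_anchors():
        put(a.graph_id, a)
    for g in doc.groups:
        put(g.graph_id, g)
        put(g.group_id, g)
    return idx


def resolve(doc: PathwayDocument, graph_ref: str) -> Optional[Element]:
    """Return the element whose graph_id (or group_id for groups) matches.

    Returns None when no element carries the reference.
    """
    return _ref_index(doc).get(graph_ref)


def validate(doc: PathwayDocument) -> list[Issue]:
    """Check document-wide invariants; returns issues, never raises.

    Errors: duplicate ids, dangling graph_ref/group_ref, malformed
    colors, non-positive drawable sizes, anchors or states outside
    their legal fraction range, interactions with fewer than 2 points.
    """
    issues: list[Issue] = []
    err = lambda eid, msg: issues.append(Issue("error", eid, msg))  # noqa: E731

    seen: dict[str, str] = {}

    def check_unique(gid: Optional[str], what: str) -> None:
        if not gid:
            return
        if gid in seen:
            err(gid, f"duplicate id {gid!r}: used by {seen[gid]} and {what}")
        else:
            seen[gid] = what

    for dn in doc.data_nodes:
        check_unique(dn.graph_id, "DataNode")
    for lab in doc.labels:
        check_unique(lab.graph_id, "Label")
    for sh in doc.shapes:
        check_unique(sh.graph_id, "Shape")
    for ia in doc.interactions:
        check_unique(ia.graph_id, "Interaction")
    for gl in doc.graphical_lines:
        check_unique(gl.graph_id, "GraphicalLine")
    for line, a in doc.iter_anchors():
        check_unique(a.graph_id, "Anchor")
        if not (0.0 <= a.position <= 1.0):
            err(a.graph_id, f"anchor position {a.position} outside [0, 1]")
    group_ids: set[str] = set()
    for g in doc.groups:
        if g.group_id in group_ids:
            err(g.group_id, f"duplicate group_id {g.group_id!r}")
        group_ids.add(g.group_id)
        check_unique(g.graph_id, "Group")
        if g.style not in GROUP_STYLES:
            err(g.group_id, f"unknown group style {g.style!r}")

    idx = _ref_index(doc)

    def check_group_ref(el_id: str, group_ref: Optional[str]) -> None:
        if group_ref is not None and group_ref not in group_ids:
            err(el_id, f"group_ref {group_ref!r} names no Group")

    def check_graphics(el_id: str, gp: GraphicsProps) -> None:
        for cname, c in (("fill_color", gp.fill_color), ("border_color", gp.border_color)):
            if not _HEX_COLOR.match(c):
                err(el_id, f"{cname} {c!r} is not RRGGBB hex")
        if gp.width <= 0 or gp.height <= 0:
            err(el_id, f"non-positive size {gp.width}x{gp.height}")
        if gp.line_style not in LINE_STYLES:
            err(el_id, f"unknown line_style {gp.line_style!r}")
        if gp.line_thickness < 0:
            err(el_id, f"negative line_thickness {gp.line_thickness}")

    for dn in doc.data_nodes:
        check_group_ref(dn.graph_id, dn.group_ref)
        check_graphics(dn.graph_id, dn.graphics)
        if dn.entity_type not in ENTITY_TYPES:
            err(dn.graph_id, f"unknown entity_type {dn.entity_type!r}")
        if dn.xref.datasource != dn.xref.datasource.strip() or dn.xref.identifier != dn.xref.identifier.strip():
            err(dn.graph_id, "xref fields carry leading/trailing whitespace")
        for st in dn.states:
            if st.graph_ref != dn.graph_id:
                err(dn.graph_id, f"state graph_ref {st.graph_ref!r} does not name its parent")
            if not (-1.0 <= st.rel_x <= 1.0 and -1.0 <= st.rel_y <= 1.0):
                err(dn.graph_id, f"state rel coords ({st.rel_x}, {st.rel_y}) outside [-1, 1]")
    for lab in doc.labels:
        check_group_ref(lab.graph_id, lab.group_ref)
        check_graphics(lab.graph_id, lab.graphics)
    for sh in doc.shapes:
        check_group_ref(sh.graph_id, sh.group_ref)
        check_graphics(sh.graph_id, sh.graphics)

    for line in [*doc.interactions, *doc.graphical_lines]:
        if len(line.points) < 2:
            err(line.graph_id, f"line has {len(line.points)} point(s); at least 2 required")
        for p in line.points:
            if p.graph_ref is not None and p.graph_ref not in idx:
                err(line.graph_id, f"point graph_ref {p.graph_ref!r} resolves to nothing")
        if isinstance(line, Interaction):
            check_group_ref(line.graph_id, line.group_ref)

    return issues


def require_valid(doc: PathwayDocument) -> None:
    """Raise InvalidDocumentError citing the first error-level issue, if any."""
    errors = [i for i in validate(doc) if i.severity == "error"]
    if errors:
        first = errors[0]
        raise InvalidDocumentError(
            f"document has {len(errors)} validation error(s); "
            f"first: [{first.element_id}] {first.message}"
        )
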
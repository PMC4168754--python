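"""View-independent graph container and the deferred-style mechanism.

During conversion of a pathway diagram, style assignments are recorded
before the nodes and edges they target exist (the drawing is walked in
document order, while e.g. anchor nodes only materialize once their
interaction is processed).  ``record_style`` therefore appends to a
plain buffer without checking targets; ``apply_styles`` resolves the
buffer against the finished graph, with last-write-wins semantics, and
fails loudly on targets that never came into existence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Iterable, Optional

import networkx as nx

NODE_KINDS = ("molecule", "group", "connector", "annotation")

STYLE_PROPERTIES = (
    "fill_color",
    "border_color",
    "border_width",
    "width",
    "height",
    "x",
    "y",
    "label",
    "shape",
    "line_style",
    "arrow_shape",
    "z_order",
    "size",
)

__all__ = [
    "Node",
    "Edge",
    "NetworkGraph",
    "DeferredStyle",
    "StyleTable",
    "record_style",
    "apply_styles",
    "StyleError",
]


class StyleError(KeyError):
    """A deferred style targets an id absent from the finished graph."""


@dataclass
class Node:
    node_id: str
    kind: str  # molecule | group | connector | annotation; immutable by convention
    attributes: dict[str, Any] = field(default_factory=dict)


@dataclass
class Edge:
    edge_id: str
    source: str
    target: str
    interaction_type: str = "undirected"
    directed: bool = False
    attributes: dict[str, Any] = field(default_factory=dict)


class NetworkGraph:
    """Typed nodes and edges with attribute tables.

    Node and edge ids are unique; edges may only reference existing
    nodes.  ``meta`` carries graph-level bookkeeping (merge statistics,
    mapping reports, ...).
    """

    def __init__(self) -> None:
        self.nodes: dict[str, Node] = {}
        self.edges: dict[str, Edge] = {}
        self.meta: dict[str, Any] = {}

    def add_node(self, node_id: str, kind: str, **attributes: Any) -> Node:
        if kind not in NODE_KINDS:
            raise ValueError(f"unknown node kind {kind!r}")
        if node_id in self.nodes:
            raise ValueError(f"duplicate node id {node_id!r}")
        node = Node(node_id, kind, attributes)
        self.nodes[node_id] = node
        return node

    def add_edge(
        self,
        edge_id: str,
        source: str,
        target: str,
        interaction_type: str = "undirected",
        directed: bool = False,
        **attributes: Any,
    ) -> Edge:
        if edge_id in self.edges:
            raise ValueError(f"duplicate edge id {edge_id!r}")
        for endpoint in (source, target):
            if endpoint not in self.nodes:
                raise ValueError(f"edge {edge_id!r} endpoint {endpoint!r} is not a node")
        edge = Edge(edge_id, source, target, interaction_type, directed, attributes)
        self.edges[edge_id] = edge
        return edge

    def nodes_of_kind(self, kind: str) -> list[Node]:
        return [n for n in self.nodes.values() if n.kind == kind]

    def to_networkx(self, *, simple_undirected: bool = False) -> nx.Graph:
        """Export to networkx; nodes and edges added in sorted-id order.

        With ``simple_undirected`` the result is an undirected simple
        graph (parallel edges and direction collapsed), the form the
        centrality metrics operate on.
        """
        g: nx.Graph = nx.Graph() if simple_undirected else nx.DiGraph()
        for nid in sorted(self.nodes):
            node = self.nodes[nid]
            g.add_node(nid, kind=node.kind, **node.attributes)
        for eid in sorted(self.edges):
            e = self.edges[eid]
            if simple_undirected:
                if e.source != e.target and not g.has_edge(e.source, e.target):
                    g.add_edge(e.source, e.target)
            else:
                g.add_edge(
                    e.source,
                    e.target,
                    edge_id=eid,
                    interaction_type=e.interaction_type,
                    directed=e.directed,
                    **e.attributes,
                )
        return g


@dataclass(frozen=True)
class DeferredStyle:
    """One recorded visual-property assignment; target may not exist yet."""

    target_id: str
    property: str
    value: Any

    def __post_init__(self) -> None:
        if self.property not in STYLE_PROPERTIES:
            raise ValueError(f"unknown style property {self.property!r}")


class StyleTable:
    """Resolved (target_id, property) -> value mapping with target classes."""

    def __init__(self) -> None:
        self._values: dict[tuple[str, str], Any] = {}
        self._classes: dict[str, str] = {}  # target_id -> "node" | "edge"

    def set(self, target_id: str, target_class: str, prop: str, value: Any) -> None:
        self._values[(target_id, prop)] = value
        self._classes[target_id] = target_class

    def get(self, target_id: str, prop: str, default: Any = None) -> Any:
        return self._values.get((target_id, prop), default)

    def items(self) -> Iterable[tuple[str, str, str, Any]]:
        for (tid, prop) in sorted(self._values):
            yield tid, self._classes[tid], prop, self._values[(tid, prop)]

    def __len__(self) -> int:
        return len(self._values)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StyleTable):
            return NotImplemented
        return self._values == other._values and self._classes == other._classes

    def to_tsv(self) -> str:
        lines = ["target_id\ttarget_class\tproperty\tvalue"]
        for tid, cls, prop, value in self.items():
            lines.append(f"{tid}\t{cls}\t{prop}\t{value}")
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        out: dict[str, dict[str, Any]] = {}
        for tid, cls, prop, value in self.items():
            entry = out.setdefault(tid, {"target_class": cls})
            entry[prop] = value
        return json.dumps(out, indent=2, sort_keys=True)


def record_style(
    buf: list[DeferredStyle], target_id: str, prop: str, value: Any
) -> list[DeferredStyle]:
    """Append a deferred assignment; later records for the same
    (target, property) win at apply time."""
    buf.append(DeferredStyle(target_id, prop, value))
    return buf


def apply_styles(graph: NetworkGraph, buf: list[DeferredStyle]) -> StyleTable:
    """Resolve a deferred-style buffer against a finished graph.

    Idempotent (same buffer twice gives an equal table) and pure with
    respect to the graph.  Raises StyleError naming the first target id
    that exists in neither the node nor the edge set.
    """
    table = StyleTable()
    for ds in buf:
        if ds.target_id in graph.nodes:
            cls = "node"
        elif ds.target_id in graph.edges:
            cls = "edge"
        else:
            raise StyleError(f"style target {ds.target_id!r} does not exist in the graph")
        table.set(ds.target_id, cls, ds.property, ds.value)
    return table
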
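"""Serialize a NetworkGraph (optionally with styles) to interchange formats.

Supported formats: GraphML (typed attribute keys, multigraph-safe),
SIF (one edge per line; attributes go to a sidecar TSV because the
format cannot carry them) and node-link JSON validating against the
schema shipped in ``pathwayviews/schemas/``.

All exporters emit in sorted order, so identical inputs give
byte-identical outputs.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Any, Optional

import networkx as nx

from .graph import NetworkGraph, StyleTable

__all__ = [
    "to_graphml",
    "to_sif",
    "to_json_graph",
    "node_attributes_tsv",
    "validate_json_graph",
    "load_json_graph_schema",
    "ExportError",
]

_SCALARS = (str, int, float, bool)


class ExportError(TypeError):
    """An attribute value cannot be represented in the target format."""


def _check_attrs(owner: str, attrs: dict[str, Any]) -> None:
    for key, value in attrs.items():
        if not isinstance(value, _SCALARS):
            raise ExportError(
                f"attribute {key!r} of {owner} has unsupported type {type(value).__name__}"
            )


def _style_attrs(styles: Optional[StyleTable], target_id: str) -> dict[str, Any]:
    if styles is None:
        return {}
    out = {}
    for tid, _cls, prop, value in styles.items():
        if tid == target_id:
            out[f"style_{prop}"] = value
    return out


def to_graphml(graph: NetworkGraph, styles: Optional[StyleTable] = None) -> str:
    """Well-formed GraphML with a declared key for every attribute.

    Style properties, when given, ride along as ``style_*`` attributes.
    Re-parsing recovers the node and edge sets exactly.
    """
    g = nx.MultiDiGraph()
    for nid in sorted(graph.nodes):
        node = graph.nodes[nid]
        attrs = {"kind": node.kind, **node.attributes, **_style_attrs(styles, nid)}
        _check_attrs(f"node {nid!r}", attrs)
        g.add_node(nid, **attrs)
    for eid in sorted(graph.edges):
        e = graph.edges[eid]
        attrs = {
            "interaction_type": e.interaction_type,
            "is_directed": e.directed,
            **e.attributes,
            **_style_attrs(styles, eid),
        }
        _check_attrs(f"edge {eid!r}", attrs)
        g.add_edge(e.source, e.target, key=eid, **attrs)
    return "\n".join(nx.generate_graphml(g, named_key_ids=True)) + "\n"


def to_sif(graph: NetworkGraph) -> str:
    """Simple Interaction Format: ``source<TAB>type<TAB>target`` per edge,
    isolated nodes as single-token lines, everything sorted."""
    connected: set[str] = set()
    lines = []
    for eid in sorted(graph.edges):
        e = graph.edges[eid]
        lines.append(f"{e.source}\t{e.interaction_type}\t{e.target}")
        connected.update((e.source, e.target))
    for nid in sorted(graph.nodes):
        if nid not in connected:
            lines.append(nid)
    return "\n".join(lines) + ("\n" if lines else "")


def node_attributes_tsv(graph: NetworkGraph) -> str:
    """Sidecar table of node attributes (SIF cannot carry them)."""
    cols: list[str] = []
    for node in graph.nodes.values():
        for key in node.attributes:
            if key not in cols:
                cols.append(key)
    lines = ["\t".join(["node_id", "kind", *cols])]
    for nid in sorted(graph.nodes):
        node = graph.nodes[nid]
        row = [nid, node.kind] + [str(node.attributes.get(c, "")) for c in cols]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def to_json_graph(graph: NetworkGraph, styles: Optional[StyleTable] = None) -> str:
    """Node-link JSON: top-level ``nodes`` and ``edges`` arrays with
    attributes inline and styles (when given) under a ``style`` key."""
    nodes = []
    for nid in sorted(graph.nodes):
        node = graph.nodes[nid]
        entry: dict[str, Any] = {"id": nid, "kind": node.kind, "attributes": dict(node.attributes)}
        style = {
            prop: value
            for tid, _cls, prop, value in (styles.items() if styles else [])
            if tid == nid
        }
        if styles is not None and style:
            entry["style"] = style
        nodes.append(entry)
    edges = []
    for eid in sorted(graph.edges):
        e = graph.edges[eid]
        entry = {
            "id": eid,
            "source": e.source,
            "target": e.target,
            "interaction_type": e.interaction_type,
            "directed": e.directed,
            "attributes": dict(e.attributes),
        }
        style = {
            prop: value
            for tid, _cls, prop, value in (styles.items() if styles else [])
            if tid == eid
        }
        if styles is not None and style:
            entry["style"] = style
        edges.append(entry)
    return json.dumps({"nodes": nodes, "edges": edges}, indent=2, sort_keys=True)


def load_json_graph_schema() -> dict[str, Any]:
    """The JSON schema the node-link export promises to satisfy."""
    text = resources.files("pathwayviews").joinpath("schemas/network_graph.schema.json").read_text()
    return json.loads(text)


def validate_json_graph(text: str) -> list[str]:
    """Check a node-link JSON document against the shipped schema's
    constraints; returns a list of violations (empty when valid)."""
    problems: list[str] = []
    try:
        obj = json.loads(text)
    except json.JSONDecodeError as e:
        return [f"not JSON: {e}"]
    if not isinstance(obj, dict):
        return ["top level is not an object"]
    for key in ("nodes", "edges"):
        if key not in obj or not isinstance(obj[key], list):
            problems.append(f"missing or non-array {key!r}")
    if problems:
        return problems
    node_ids = set()
    for i, n in enumerate(obj["nodes"]):
        for req, typ in (("id", str), ("kind", str), ("attributes", dict)):
            if req not in n or not isinstance(n[req], typ):
                problems.append(f"nodes[{i}]: missing or mistyped {req!r}")
        if isinstance(n.get("id"), str):
            if n["id"] in node_ids:
                problems.append(f"nodes[{i}]: duplicate id {n['id']!r}")
            node_ids.add(n["id"])
    for i, e in enumerate(obj["edges"]):
        for req, typ in (
            ("id", str),
            ("source", str),
            ("target", str),
            ("interaction_type", str),
            ("directed", bool),
            ("attributes", dict),
        ):
            if req not in e or not isinstance(e[req], typ):
                problems.append(f"edges[{i}]: missing or mistyped {req!r}")
        for end in ("source", "target"):
            if isinstance(e.get(end), str) and e[end] not in node_ids:
                problems.append(f"edges[{i}]: {end} {e[end]!r} is not a node id")
    return problems
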
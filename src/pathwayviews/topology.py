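"""Degree and betweenness centrality for the network view.

Both metrics treat the graph as undirected and simple: edge direction
is ignored and collapsed parallel edges count once, the convention of
Cytoscape's NetworkAnalyzer for mixed graphs.  Betweenness is
unnormalized shortest-path betweenness (Brandes), endpoints excluded,
with each unordered pair counted once and equal-length shortest paths
splitting the count evenly.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from .graph import NetworkGraph

__all__ = ["degree", "betweenness", "centrality_table", "centrality_tsv"]


def degree(graph: NetworkGraph) -> dict[str, int]:
    """Undirected simple degree of every node (multiplicity counts as 1)."""
    g = graph.to_networkx(simple_undirected=True)
    return {nid: int(d) for nid, d in g.degree()}


def betweenness(graph: NetworkGraph, normalized: bool = False) -> dict[str, float]:
    """Shortest-path betweenness of every node on the undirected simple graph.

    Unnormalized by default: the score of v is the number of unordered
    pairs (s, t), s != v != t, whose shortest paths pass through v,
    fractional when several shortest paths tie.
    """
    g = graph.to_networkx(simple_undirected=True)
    bc = nx.betweenness_centrality(g, normalized=normalized)
    return {nid: float(v) for nid, v in bc.items()}


def centrality_table(graph: NetworkGraph, normalized: bool = False) -> pd.DataFrame:
    """Degree and betweenness for every node, indexed by node_id."""
    deg = degree(graph)
    btw = betweenness(graph, normalized=normalized)
    ids = sorted(graph.nodes)
    return pd.DataFrame(
        {"degree": [deg[i] for i in ids], "betweenness": [btw[i] for i in ids]},
        index=pd.Index(ids, name="node_id"),
    )


def centrality_tsv(graph: NetworkGraph, normalized: bool = False) -> str:
    return centrality_table(graph, normalized=normalized).to_csv(sep="\t")
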
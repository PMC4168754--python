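"""Deterministic synthetic GPML pathways and matching demo data.

Every module is testable offline: ``make_fixture`` builds a valid
pathway document with a controllable amount of redundancy (data nodes
sharing a cross-reference), groups, interactions with anchors, labels
and shapes, all laid out on a grid; ``make_demo_data`` derives a
matching expression table (logFC, p-value, Benjamini–Hochberg adjusted
p-value) plus an Entrez→Ensembl-style mapping table, mirroring the
classic differentiation-experiment overlay workflow.

Both generators are pure functions of their spec and seed.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass

import pandas as pd
from statsmodels.stats.multitest import multipletests

from .model import (
    Anchor,
    DataNode,
    GraphicsProps,
    Group,
    Interaction,
    Label,
    PathwayDocument,
    Point,
    Shape,
    Xref,
)

__all__ = [
    "FixtureSpec",
    "make_fixture",
    "make_demo_data",
    "canonical_fixture_spec",
    "canonical_fixture",
    "data_table_tsv",
    "mapping_table_tsv",
]

#: standard deviation of the simulated log fold-changes
LOGFC_SD = 1.5


@dataclass(frozen=True)
class FixtureSpec:
    """Shape of a generated pathway document."""

    n_datanodes: int = 5
    n_redundant_pairs: int = 0
    n_groups: int = 0
    group_size: int = 2
    n_interactions: int = 0
    n_anchors: int = 0
    n_labels: int = 0
    n_shapes: int = 0
    seed: int = 0

    def check(self) -> None:
        if min(self.n_datanodes, self.n_redundant_pairs, self.n_groups,
               self.n_interactions, self.n_anchors, self.n_labels, self.n_shapes) < 0:
            raise ValueError("negative counts are infeasible")
        if self.group_size < 2:
            raise ValueError("group_size must be >= 2")
        if self.n_redundant_pairs > self.n_datanodes // 2:
            raise ValueError("more redundant pairs than data-node pairs")
        if self.n_anchors > self.n_interactions:
            raise ValueError("more anchors than interactions")
        if self.n_groups * self.group_size > self.n_datanodes:
            raise ValueError("groups demand more members than there are data nodes")
        if self.n_interactions > 0 and self.n_datanodes < 2:
            raise ValueError("interactions need at least 2 data nodes")


def canonical_fixture_spec() -> FixtureSpec:
    """The small reference pathway used throughout the test suite."""
    return FixtureSpec(
        n_datanodes=5,
        n_redundant_pairs=1,
        n_groups=1,
        group_size=2,
        n_interactions=3,
        n_anchors=1,
        n_labels=1,
        n_shapes=1,
        seed=7,
    )


def canonical_fixture() -> PathwayDocument:
    return make_fixture(canonical_fixture_spec())


def _grid(i: int) -> tuple[float, float]:
    return 100.0 + 150.0 * (i % 5), 100.0 + 100.0 * (i // 5)


def make_fixture(spec: FixtureSpec) -> PathwayDocument:
    """Generate a pathway document satisfying the spec exactly.

    Guarantees: validates with zero issues; exactly ``n_redundant_pairs``
    pairs of data nodes share a cross-reference (first nodes in index
    order pair up); groups take their members from the tail of the
    data-node list so grouping and redundancy do not interact; every
    interaction endpoint resolves.  Identical specs give identical
    documents.
    """
    spec.check()
    rng = random.Random(spec.seed)
    doc = PathwayDocument(
        name=f"Synthetic pathway (seed {spec.seed})",
        organism="Homo sapiens",
        board_width=900.0,
        board_height=600.0,
    )

    # data nodes; node 2j and 2j+1 share an Entrez id for j < n_redundant_pairs
    for i in range(spec.n_datanodes):
        if i < 2 * spec.n_redundant_pairs:
            entrez = str(1000 + i // 2)
        else:
            entrez = str(1000 + i - spec.n_redundant_pairs)
        cx, cy = _grid(i)
        doc.data_nodes.append(
            DataNode(
                graph_id=f"dn{i}",
                text_label=f"GENE{i}",
                entity_type="GeneProduct",
                xref=Xref("Entrez Gene", entrez),
                graphics=GraphicsProps(center_x=cx, center_y=cy, width=80.0, height=20.0),
            )
        )

    # groups claim members from the tail of the data-node list
    member_idx = spec.n_datanodes - spec.n_groups * spec.group_size
    for j in range(spec.n_groups):
        gid = f"grp{j}"
        doc.groups.append(Group(group_id=gid, graph_id=f"g{j}", style="Group"))
        for _ in range(spec.group_size):
            doc.data_nodes[member_idx].group_ref = gid
            member_idx += 1

    # interactions between distinct data nodes; the first n_anchors carry
    # one mid-line anchor each
    for t in range(spec.n_interactions):
        src = rng.randrange(spec.n_datanodes)
        tgt = rng.randrange(spec.n_datanodes - 1)
        if tgt >= src:
            tgt += 1
        a, b = doc.data_nodes[src], doc.data_nodes[tgt]
        anchors = [Anchor(graph_id=f"anch{t}", position=0.5)] if t < spec.n_anchors else []
        doc.interactions.append(
            Interaction(
                graph_id=f"ia{t}",
                points=[
                    Point(a.graphics.center_x, a.graphics.center_y, graph_ref=a.graph_id),
                    Point(b.graphics.center_x, b.graphics.center_y, graph_ref=b.graph_id,
                          arrow_head="Arrow"),
                ],
                anchors=anchors,
            )
        )

    base = spec.n_datanodes
    for i in range(spec.n_labels):
        cx, cy = _grid(base + i)
        doc.labels.append(
            Label(
                graph_id=f"lab{i}",
                text_label=f"Region {i}",
                graphics=GraphicsProps(center_x=cx, center_y=cy, width=90.0, height=16.0),
            )
        )
    base += spec.n_labels
    for i in range(spec.n_shapes):
        cx, cy = _grid(base + i)
        doc.shapes.append(
            Shape(
                graph_id=f"shp{i}",
                graphics=GraphicsProps(
                    center_x=cx, center_y=cy, width=120.0, height=80.0, shape_name="Oval"
                ),
            )
        )
    return doc


def _normal_sf(z: float) -> float:
    """Upper-tail probability of the standard normal."""
    return 0.5 * math.erfc(z / math.sqrt(2.0))


def make_demo_data(
    doc: PathwayDocument, seed: int = 0, unmeasured_fraction: float = 0.2
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Expression table and identifier mapping matching a document.

    One data row per distinct gene cross-reference: logFC drawn from
    Normal(0, 1.5), a two-sided p-value consistent with that effect
    size, and Benjamini–Hochberg adjusted p-values (adjusted >= raw).
    A fraction of the genes (rounded up, default 0.2) is deliberately
    left out of the mapping table so some pathway nodes stay
    unmeasured and exercise the grey-fill path; fraction 0 measures
    every node.

    Raises ValueError when the document has no cross-referenced nodes.
    """
    xref_ids: list[str] = []
    for dn in doc.data_nodes:
        if not dn.xref.is_empty() and dn.xref.identifier not in xref_ids:
            xref_ids.append(dn.xref.identifier)
    if not xref_ids:
        raise ValueError("document has no data node with a cross-reference")

    rng = random.Random(seed)
    mapping = {src: [f"ENSGTEST{i:08d}"] for i, src in enumerate(xref_ids)}

    n_unmeasured = math.ceil(len(xref_ids) * unmeasured_fraction) if unmeasured_fraction > 0 else 0
    n_unmeasured = min(n_unmeasured, len(xref_ids))
    for src in rng.sample(xref_ids, n_unmeasured):
        del mapping[src]

    targets = [f"ENSGTEST{i:08d}" for i in range(len(xref_ids))]
    logfc = [rng.gauss(0.0, LOGFC_SD) for _ in targets]
    pvals = [min(1.0, 2.0 * _normal_sf(abs(fc) / LOGFC_SD)) for fc in logfc]
    adj = multipletests(pvals, method="fdr_bh")[1]
    df = pd.DataFrame(
        {"logFC": logfc, "p_value": pvals, "adj_p_value": adj},
        index=pd.Index(targets, name="id"),
    )
    return df, mapping


def data_table_tsv(df: pd.DataFrame) -> str:
    return df.to_csv(sep="\t", float_format="%.10g")


def mapping_table_tsv(mapping: dict[str, list[str]]) -> str:
    lines = ["# source\ttarget"]
    for src, targets in mapping.items():
        for tgt in targets:
            lines.append(f"{src}\t{tgt}")
    return "\n".join(lines) + "\n"
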
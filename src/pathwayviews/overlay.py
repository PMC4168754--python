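"""Identifier mapping and experimental-data overlay.

The workflow mirrors the classic pathway-analysis demonstration: gene
identifiers drawn in the pathway (e.g. Entrez Gene) are translated to
the identifier system of the expression data (e.g. Ensembl) through a
two-column mapping table, the measurements are joined onto the molecule
nodes, and visual styles encode the result —

* node fill follows a blue–white–red gradient over log fold-change,
  symmetric about zero;
* a green border marks significant measurements (adjusted p-value
  strictly below alpha);
* molecules without a measurement are filled grey.

Degree/betweenness styling for hub-spotting reuses the same gradient
machinery with node size tracking degree.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .graph import DeferredStyle, NetworkGraph, StyleTable, apply_styles, record_style

logger = logging.getLogger(__name__)

__all__ = [
    "VisualMapping",
    "read_data_table",
    "read_mapping_table",
    "map_identifiers",
    "join_data",
    "gradient_color",
    "apply_data_styles",
    "centrality_styles",
    "DataJoinError",
]

DATA_COLUMNS = ("logFC", "p_value", "adj_p_value")


class DataJoinError(ValueError):
    """The data table cannot be joined (e.g. duplicated identifiers)."""


@dataclass
class VisualMapping:
    """Parameters of the data-to-style mapping.

    ``domain_limit`` is the gradient half-width L: logFC −L maps to the
    low color, 0 to the mid color, +L to the high color, clamping
    beyond.  When None, L defaults to max |logFC| over the measured
    nodes at apply time.
    """

    gradient_low_color: str = "0000FF"
    mid_color: str = "FFFFFF"
    high_color: str = "FF0000"
    domain_limit: Optional[float] = None
    alpha: float = 0.05
    significant_border_color: str = "00FF00"
    missing_fill_color: str = "C8C8C8"
    default_border_color: str = "000000"

    def __post_init__(self) -> None:
        if self.domain_limit is not None and self.domain_limit <= 0:
            raise ValueError("domain_limit must be > 0")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie strictly between 0 and 1")


def read_data_table(
    source: Union[str, Path, io.StringIO], id_column: str = "id", sep: Optional[str] = None
) -> pd.DataFrame:
    """Read a measurement table (TSV/CSV with header) indexed by identifier.

    Rows whose p-values fall outside [0, 1] are rejected with a
    warning.  Duplicate identifiers are kept here; ``join_data`` errors
    on them so the caller sees exactly which join failed.
    """
    if sep is None:
        sep = "," if str(source).endswith(".csv") else "\t"
    df = pd.read_csv(source, sep=sep, comment="#", dtype={id_column: str})
    if id_column not in df.columns:
        raise DataJoinError(f"data table lacks identifier column {id_column!r}")
    df = df.set_index(id_column)
    for col in ("p_value", "adj_p_value"):
        if col in df.columns:
            bad = df[(df[col] < 0) | (df[col] > 1)].index
            if len(bad):
                logger.warning("rejecting %d row(s) with %s outside [0, 1]: %s",
                               len(bad), col, list(bad))
                df = df.drop(index=bad)
    return df


def read_mapping_table(source: Union[str, Path, io.StringIO]) -> dict[str, list[str]]:
    """Read a two-column source→target mapping (TSV, '#' comments allowed).

    One source id may map to several targets; list order follows the
    file, duplicates within one source are dropped.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    mapping: dict[str, list[str]] = {}
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
            raise ValueError(f"mapping line {ln} is not two non-empty tab-separated ids: {raw!r}")
        src, tgt = parts[0].strip(), parts[1].strip()
        targets = mapping.setdefault(src, [])
        if tgt not in targets:
            targets.append(tgt)
    return mapping


def map_identifiers(graph: NetworkGraph, mapping: dict[str, list[str]]) -> NetworkGraph:
    """Annotate molecule nodes with ``mapped_id`` via table lookup.

    One-to-many mappings resolve to the first target in file order; the
    ambiguity count and unmapped count land in ``graph.meta`` (the
    mapping report).  Nodes without an entry get ``unmapped=True``.
    """
    if not mapping:
        logger.warning("empty mapping table: every node will be unmapped")
    ambiguous = 0
    unmapped = 0
    for node in graph.nodes_of_kind("molecule"):
        src = node.attributes.get("xref_identifier", "")
        targets = mapping.get(src)
        if targets:
            node.attributes["mapped_id"] = targets[0]
            node.attributes.pop("unmapped", None)
            if len(targets) > 1:
                ambiguous += 1
        else:
            node.attributes.pop("mapped_id", None)
            node.attributes["unmapped"] = True
            unmapped += 1
    graph.meta["mapping_report"] = {"ambiguous": ambiguous, "unmapped": unmapped}
    if ambiguous:
        logger.warning("%d identifier(s) mapped ambiguously; first target kept", ambiguous)
    return graph


def join_data(graph: NetworkGraph, data: pd.DataFrame) -> NetworkGraph:
    """Exact-match join of measurements onto molecule nodes by ``mapped_id``.

    Idempotent.  Raises DataJoinError before touching the graph when
    the data table's identifiers are not unique.  A merged node whose
    constituent identifiers hit different measurements keeps the
    representative's value and is flagged ``data_conflict=True``.
    """
    dup = data.index[data.index.duplicated()].unique()
    if len(dup):
        raise DataJoinError(f"duplicated identifier(s) in data table: {list(dup)}")
    measured = 0
    for node in graph.nodes_of_kind("molecule"):
        mid = node.attributes.get("mapped_id", node.attributes.get("xref_identifier"))
        if mid is not None and mid in data.index:
            row = data.loc[mid]
            for col in DATA_COLUMNS:
                if col in data.columns:
                    node.attributes[col] = float(row[col])
            measured += 1
        else:
            for col in DATA_COLUMNS:
                node.attributes.pop(col, None)
    graph.meta["measured_count"] = measured
    return graph


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _lerp_hex(c0: str, c1: str, t: float) -> str:
    channels = []
    for i in (0, 2, 4):
        a = int(c0[i : i + 2], 16)
        b = int(c1[i : i + 2], 16)
        channels.append(_round_half_up(a + (b - a) * t))
    return "".join(f"{c:02X}" for c in channels)


def gradient_color(logfc: float, vm: VisualMapping) -> Optional[str]:
    """Piecewise-linear blue–white–red color for one logFC value.

    −L maps to the low color, 0 to the mid color, +L to the high
    color; values beyond ±L clamp to the endpoints; channel rounding is
    half-up.  Non-finite input is treated as missing (returns None).
    """
    if logfc is None or not math.isfinite(logfc):
        return None
    L = vm.domain_limit
    if L is None or L <= 0:
        raise ValueError("gradient requires a positive domain_limit")
    x = max(-L, min(L, logfc))
    if x >= 0:
        return _lerp_hex(vm.mid_color, vm.high_color, x / L)
    return _lerp_hex(vm.mid_color, vm.gradient_low_color, -x / L)


def _resolved(vm: VisualMapping, graph: NetworkGraph) -> VisualMapping:
    if vm.domain_limit is not None:
        return vm
    fcs = [
        abs(n.attributes["logFC"])
        for n in graph.nodes_of_kind("molecule")
        if "logFC" in n.attributes and math.isfinite(n.attributes["logFC"])
    ]
    limit = max(fcs) if fcs and max(fcs) > 0 else 1.0
    out = VisualMapping(**{**vm.__dict__, "domain_limit": limit})
    return out


def apply_data_styles(graph: NetworkGraph, vm: Optional[VisualMapping] = None) -> StyleTable:
    """Style molecule nodes from their joined measurements.

    Measured nodes get the gradient fill and, when adj_p_value < alpha
    (strict), the significant border color; unmeasured ones the grey
    missing fill with the default border.  Group/connector/annotation
    nodes are untouched.  Deterministic and idempotent.
    """
    vm = _resolved(vm or VisualMapping(), graph)
    buf: list[DeferredStyle] = []
    for nid in sorted(graph.nodes):
        node = graph.nodes[nid]
        if node.kind != "molecule":
            continue
        fill = None
        if "logFC" in node.attributes:
            fill = gradient_color(node.attributes["logFC"], vm)
        if fill is None:
            record_style(buf, nid, "fill_color", vm.missing_fill_color)
            record_style(buf, nid, "border_color", vm.default_border_color)
            continue
        record_style(buf, nid, "fill_color", fill)
        adj_p = node.attributes.get("adj_p_value")
        significant = adj_p is not None and math.isfinite(adj_p) and adj_p < vm.alpha
        record_style(
            buf,
            nid,
            "border_color",
            vm.significant_border_color if significant else vm.default_border_color,
        )
    return apply_styles(graph, buf)


def centrality_styles(
    graph: NetworkGraph,
    degrees: dict[str, int],
    betweenness: dict[str, float],
    size_range: tuple[float, float] = (20.0, 80.0),
    vm: Optional[VisualMapping] = None,
) -> StyleTable:
    """Visualize hubs: node size linear in degree over ``size_range``,
    fill from betweenness through the same color gradient.

    A constant metric places every node mid-range (the spread is
    undefined); higher degree never yields a smaller node.
    """
    vm = vm or VisualMapping(domain_limit=1.0)
    if vm.domain_limit is None:
        vm = VisualMapping(**{**vm.__dict__, "domain_limit": 1.0})
    lo, hi = size_range
    buf: list[DeferredStyle] = []
    ids = sorted(graph.nodes)
    dmin, dmax = min(degrees.values()), max(degrees.values())
    bmin, bmax = min(betweenness.values()), max(betweenness.values())
    L = vm.domain_limit
    for nid in ids:
        if dmax == dmin:
            size = (lo + hi) / 2
        else:
            size = lo + (hi - lo) * (degrees[nid] - dmin) / (dmax - dmin)
        record_style(buf, nid, "size", size)
        if bmax == bmin:
            fill = vm.mid_color
        else:
            t = (betweenness[nid] - bmin) / (bmax - bmin)  # in [0, 1]
            fill = gradient_color((2 * t - 1) * L, vm)
        record_style(buf, nid, "fill_color", fill)
    return apply_styles(graph, buf)
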
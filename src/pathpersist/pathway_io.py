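"""Reading and writing directed pathway networks.

Pathway topologies come either from KGML (the KEGG Markup Language XML
format) or from plain edge-list / adjacency-matrix tables.  All readers
normalise to :class:`PathwayNetwork`: a simple directed graph on gene
symbols with a coarse relation label per edge (``activation``,
``inhibition`` or ``other``).  The label is provenance only — it never
enters the homology computation, where an edge is an edge.
"""

from __future__ import annotations

import io
import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

#: relation labels recognised on edges
RELATIONS = ("activation", "inhibition", "other")

# KGML relation subtypes that map onto activation / inhibition; everything
# else (expression, binding/association, indirect effect, ...) is "other".
_KGML_SUBTYPE_MAP = {
    "activation": "activation",
    "inhibition": "inhibition",
}


class PathwayParseError(ValueError):
    """Raised when a pathway document cannot be interpreted."""


@dataclass
class PathwayNetwork:
    """A directed gene-interaction network.

    Invariants (enforced by :meth:`validate`): unique node symbols, no
    self-loops, every edge endpoint a node, at most one edge per ordered
    (source, target) pair.  A mutual interaction A<->B is stored as the two
    distinct directed edges A->B and B->A.
    """

    pathway_id: str
    name: str = ""
    nodes: list[str] = field(default_factory=list)
    edges: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node symbols")
        node_set = set(self.nodes)
        seen: set[tuple[str, str]] = set()
        for src, dst, rel in self.edges:
            if src == dst:
                raise ValueError(f"self-loop {src}->{dst} not permitted")
            if src not in node_set or dst not in node_set:
                raise ValueError(f"edge endpoint not in nodes: {src}->{dst}")
            if (src, dst) in seen:
                raise ValueError(f"duplicate edge {src}->{dst}")
            if rel not in RELATIONS:
                raise ValueError(f"unknown relation label {rel!r}")
            seen.add((src, dst))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_pairs(self) -> list[tuple[str, str]]:
        """Ordered (source, target) pairs without relation labels."""
        return [(s, t) for s, t, _ in self.edges]

    def subnetwork(self, keep_nodes: set[str]) -> "PathwayNetwork":
        """Induced subgraph on ``keep_nodes`` (order preserved)."""
        nodes = [n for n in self.nodes if n in keep_nodes]
        edges = [
            (s, t, r) for s, t, r in self.edges if s in keep_nodes and t in keep_nodes
        ]
        return PathwayNetwork(self.pathway_id, self.name, nodes, edges)


def _add_edge(
    nodes: list[str],
    node_set: set[str],
    edge_map: dict[tuple[str, str], str],
    src: str,
    dst: str,
    rel: str,
    *,
    context: str,
) -> None:
    """Accumulate an edge, dropping self-loops and merging duplicates."""
    if src == dst:
        logger.warning("%s: dropping self-loop %s->%s", context, src, dst)
        return
    for v in (src, dst):
        if v not in node_set:
            node_set.add(v)
            nodes.append(v)
    key = (src, dst)
    if key in edge_map:
        # keep the more specific label on collision
        if edge_map[key] == "other" and rel != "other":
            edge_map[key] = rel
        return
    edge_map[key] = rel


def parse_kgml(
    kgml_document: str,
    id_map: dict[str, str] | None = None,
) -> PathwayNetwork:
    """Parse a KGML document into a :class:`PathwayNetwork`.

    Gene-type ``entry`` elements become nodes (one node per identifier in
    the entry's whitespace-separated ``name`` attribute; multi-identifier
    entries are group-like and are expanded so each identifier inherits all
    of the entry's relations).  ``relation`` elements between gene entries
    become directed edges; relation subtypes map onto
    activation / inhibition / other.  Compound, map and other non-gene
    entries are dropped, as are self-loops (with a warning).

    Parameters
    ----------
    kgml_document:
        The KGML XML text.
    id_map:
        Optional identifier -> gene-symbol table (e.g. ``hsa:7157`` ->
        ``TP53``).  Unmapped identifiers keep their raw id; a warning is
        logged once per unmapped id.
    """
    try:
        root = ET.fromstring(kgml_document)
    except ET.ParseError as exc:
        raise PathwayParseError(f"malformed KGML XML: {exc}") from exc
    if root.tag != "pathway":
        raise PathwayParseError(f"expected <pathway> root, found <{root.tag}>")

    id_map = id_map or {}
    unmapped: set[str] = set()

    def symbol(raw: str) -> str:
        if raw in id_map:
            return id_map[raw]
        if raw not in unmapped:
            unmapped.add(raw)
            logger.warning("KGML id %s has no symbol mapping; keeping raw id", raw)
        return raw

    # entry id -> list of gene symbols (gene entries only)
    entry_genes: dict[str, list[str]] = {}
    # entry id -> member entry ids (group entries)
    entry_groups: dict[str, list[str]] = {}
    known_ids: set[str] = set()
    for entry in root.findall("entry"):
        eid = entry.get("id", "")
        etype = entry.get("type", "")
        known_ids.add(eid)
        if etype == "gene":
            names = (entry.get("name") or "").split()
            entry_genes[eid] = [symbol(n) for n in names]
        elif etype == "group":
            entry_groups[eid] = [
                comp.get("id", "") for comp in entry.findall("component")
            ]
        # compounds, maps, orthologs etc. are intentionally ignored

    def resolve(eid: str) -> list[str]:
        """Gene symbols reachable from an entry id (through groups)."""
        if eid in entry_genes:
            return entry_genes[eid]
        if eid in entry_groups:
            out: list[str] = []
            for member in entry_groups[eid]:
                out.extend(resolve(member))
            return out
        return []

    nodes: list[str] = []
    node_set: set[str] = set()
    for eid in entry_genes:
        for sym in entry_genes[eid]:
            if sym not in node_set:
                node_set.add(sym)
                nodes.append(sym)

    edge_map: dict[tuple[str, str], str] = {}
    pid = root.get("name", root.get("number", "unknown"))
    for relation in root.findall("relation"):
        e1, e2 = relation.get("entry1", ""), relation.get("entry2", "")
        for eid in (e1, e2):
            if eid not in known_ids:
                raise PathwayParseError(
                    f"relation references unknown entry id {eid!r}"
                )
        rel = "other"
        for subtype in relation.findall("subtype"):
            mapped = _KGML_SUBTYPE_MAP.get(subtype.get("name", ""))
            if mapped:
                rel = mapped
                break
        for src in resolve(e1):
            for dst in resolve(e2):
                _add_edge(nodes, node_set, edge_map, src, dst, rel, context=pid)

    return PathwayNetwork(
        pathway_id=pid,
        name=root.get("title", ""),
        nodes=nodes,
        edges=[(s, t, r) for (s, t), r in edge_map.items()],
    )


def expand_group_nodes(
    network: PathwayNetwork, groups: dict[str, list[str]]
) -> PathwayNetwork:
    """Replace group nodes by their member genes.

    Every edge incident to a group node is duplicated onto every member, so
    each separated gene keeps all interactions of the original group.  A
    member colliding with an existing node is merged (edges unioned, with a
    warning); an empty group is an error.
    """
    for g, members in groups.items():
        if not members:
            raise ValueError(f"group {g!r} has no members")
        if g not in network.nodes:
            raise ValueError(f"group {g!r} is not a node of the network")

    nodes = [n for n in network.nodes if n not in groups]
    node_set = set(nodes)
    for g in network.nodes:
        if g not in groups:
            continue
        for sym in groups[g]:
            if sym in node_set:
                logger.warning(
                    "group member %s collides with existing node; merging", sym
                )
                continue
            node_set.add(sym)
            nodes.append(sym)

    edge_map: dict[tuple[str, str], str] = {}
    for src, dst, rel in network.edges:
        for s in groups.get(src, [src]):
            for t in groups.get(dst, [dst]):
                _add_edge(nodes, node_set, edge_map, s, t, rel,
                          context=network.pathway_id)

    return PathwayNetwork(
        pathway_id=network.pathway_id,
        name=network.name,
        nodes=nodes,
        edges=[(s, t, r) for (s, t), r in edge_map.items()],
    )


def read_edge_list(table: str | io.TextIOBase, pathway_id: str = "pathway") -> PathwayNetwork:
    """Read a TSV edge list with columns ``source``, ``target`` [, ``relation``].

    Duplicate rows collapse to a single edge; self-loop rows are dropped
    with a warning.
    """
    if isinstance(table, str):
        table = io.StringIO(table)
    df = pd.read_csv(table, sep="\t", dtype=str)
    missing = {"source", "target"} - set(df.columns)
    if missing:
        raise PathwayParseError(f"edge list missing columns: {sorted(missing)}")
    nodes: list[str] = []
    node_set: set[str] = set()
    edge_map: dict[tuple[str, str], str] = {}
    for row in df.itertuples(index=False):
        src = str(row.source)
        if pd.isna(row.target) or str(row.target) == "":
            # isolated-node row
            if src not in node_set:
                node_set.add(src)
                nodes.append(src)
            continue
        rel = getattr(row, "relation", "other")
        if pd.isna(rel) or rel not in RELATIONS:
            rel = "other"
        _add_edge(nodes, node_set, edge_map, src, str(row.target), rel,
                  context=pathway_id)
    return PathwayNetwork(
        pathway_id=pathway_id,
        nodes=nodes,
        edges=[(s, t, r) for (s, t), r in edge_map.items()],
    )


def write_edge_list(network: PathwayNetwork) -> str:
    """Serialise a network as the TSV edge list read by :func:`read_edge_list`.

    Isolated nodes are written as rows with an empty target so the round
    trip preserves the node set exactly.
    """
    lines = ["source\ttarget\trelation"]
    touched = {v for s, t, _ in network.edges for v in (s, t)}
    for s, t, r in network.edges:
        lines.append(f"{s}\t{t}\t{r}")
    for n in network.nodes:
        if n not in touched:
            lines.append(f"{n}\t\t")
    return "\n".join(lines) + "\n"


def read_adjacency(table: str | io.TextIOBase, pathway_id: str = "pathway") -> PathwayNetwork:
    """Read a CSV adjacency matrix (symbols as row/column labels, 1 = edge row->column)."""
    if isinstance(table, str):
        table = io.StringIO(table)
    df = pd.read_csv(table, index_col=0)
    if list(df.index) != list(df.columns):
        raise PathwayParseError("adjacency matrix row and column labels differ")
    nodes = [str(n) for n in df.index]
    edges = []
    for i, src in enumerate(nodes):
        for j, dst in enumerate(nodes):
            if df.iat[i, j]:
                if src == dst:
                    logger.warning("%s: dropping self-loop %s", pathway_id, src)
                    continue
                edges.append((src, dst, "other"))
    return PathwayNetwork(pathway_id=pathway_id, nodes=nodes, edges=edges)


def write_adjacency(network: PathwayNetwork) -> str:
    """Serialise as the CSV adjacency matrix read by :func:`read_adjacency`."""
    nodes = network.nodes
    idx = {n: i for i, n in enumerate(nodes)}
    mat = [[0] * len(nodes) for _ in nodes]
    for s, t, _ in network.edges:
        mat[idx[s]][idx[t]] = 1
    lines = ["," + ",".join(nodes)]
    for n, row in zip(nodes, mat):
        lines.append(n + "," + ",".join(str(v) for v in row))
    return "\n".join(lines) + "\n"
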
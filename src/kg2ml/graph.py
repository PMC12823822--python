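"""Heterogeneous property graph: typed nodes keyed by CUI, undirected adjacency.

The graph is the substrate every downstream stage traverses: label
extraction walks 2-hop metapaths over it, and the feature builder reads
Gene-EFO adjacency from it.  Nodes are keyed by their UMLS Concept Unique
Identifier (CUI); node types come from a small declared vocabulary
(Disease, Compound, Gene, EFO) with anything else preserved as-is.
Traversal is undirected: edge direction in the input tables is kept on the
edge records but ignored for adjacency, and parallel edges between the
same pair of nodes collapse to a single adjacency entry (relation
multiplicity survives only in the edge collection).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "KNOWN_NODE_TYPES",
    "NodeRecord",
    "EdgeRecord",
    "PropertyGraph",
    "GraphFormatError",
    "GraphIntegrityError",
    "load_graph",
    "write_graph",
    "condense",
    "neighbors",
]

#: Node types with dedicated roles in the pipeline.  Anything outside this
#: vocabulary is legal input and is carried through unchanged.
KNOWN_NODE_TYPES = frozenset({"Disease", "Compound", "Gene", "EFO"})

NODE_COLUMNS = ("cui", "node_type", "display_label")
EDGE_COLUMNS = ("source_cui", "target_cui", "relation_type", "provenance_sab")


class GraphFormatError(ValueError):
    """Raised when an input table is missing required columns."""


class GraphIntegrityError(ValueError):
    """Raised on referential or uniqueness violations in graph tables."""


@dataclass(frozen=True)
class NodeRecord:
    cui: str
    node_type: str
    display_label: str = ""

    def __post_init__(self) -> None:
        if not self.cui:
            raise GraphIntegrityError("node CUI must be non-empty")


@dataclass(frozen=True)
class EdgeRecord:
    source_cui: str
    target_cui: str
    relation_type: str = ""
    provenance_sab: str = ""


@dataclass
class PropertyGraph:
    """Typed undirected graph over CUI-keyed nodes.

    ``adjacency`` maps every CUI to the set of its neighbor CUIs and is
    kept symmetric; self-loops are dropped.  ``edges`` retains every input
    edge record (including parallel relations) for provenance.
    """

    nodes: dict[str, NodeRecord] = field(default_factory=dict)
    edges: list[EdgeRecord] = field(default_factory=list)
    adjacency: dict[str, set[str]] = field(default_factory=dict)

    @classmethod
    def from_records(
        cls,
        nodes: Iterable[NodeRecord],
        edges: Iterable[EdgeRecord],
        strict: bool = True,
    ) -> "PropertyGraph":
        """Build and validate a graph from node and edge records.

        With ``strict`` (default), edges whose endpoints are not declared as
        nodes raise :class:`GraphIntegrityError` naming the offending CUIs;
        otherwise they are silently dropped and counted in
        ``g.n_rejected_edges``.
        """
        g = cls()
        for rec in nodes:
            prior = g.nodes.get(rec.cui)
            if prior is not None:
                if prior.node_type != rec.node_type:
                    raise GraphIntegrityError(
                        f"duplicate CUI {rec.cui!r} with conflicting node_type "
                        f"({prior.node_type!r} vs {rec.node_type!r})"
                    )
                continue
            g.nodes[rec.cui] = rec
            g.adjacency[rec.cui] = set()
        missing: set[str] = set()
        n_rejected = 0
        for e in edges:
            unknown = {c for c in (e.source_cui, e.target_cui) if c not in g.nodes}
            if unknown:
                missing |= unknown
                n_rejected += 1
                continue
            g.edges.append(e)
            if e.source_cui != e.target_cui:
                g.adjacency[e.source_cui].add(e.target_cui)
                g.adjacency[e.target_cui].add(e.source_cui)
        if missing and strict:
            raise GraphIntegrityError(
                "edges reference CUIs absent from the node table: "
                + ", ".join(sorted(missing))
            )
        g.n_rejected_edges = n_rejected  # type: ignore[attr-defined]
        return g

    @property
    def node_types(self) -> set[str]:
        return {rec.node_type for rec in self.nodes.values()}

    def nodes_of_type(self, node_type: str) -> set[str]:
        return {c for c, rec in self.nodes.items() if rec.node_type == node_type}

    def __contains__(self, cui: str) -> bool:
        return cui in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)


def _read_table(path: str | Path, columns: tuple[str, ...], delimiter: str) -> list[dict]:
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        missing = [c for c in columns if c not in header]
        if missing:
            raise GraphFormatError(
                f"{path}: missing required column(s) {missing}; found {header}"
            )
        return [{c: (row[c] or "") for c in columns} for row in reader]


def load_graph(
    nodes_table: str | Path,
    edges_table: str | Path,
    delimiter: str = "\t",
    strict: bool = True,
) -> PropertyGraph:
    """Load a property graph from delimited node and edge tables.

    The node table must carry columns ``cui, node_type, display_label`` and
    the edge table ``source_cui, target_cui, relation_type, provenance_sab``
    (header row required; tab-delimited by default).
    """
    node_rows = _read_table(nodes_table, NODE_COLUMNS, delimiter)
    edge_rows = _read_table(edges_table, EDGE_COLUMNS, delimiter)
    return PropertyGraph.from_records(
        (NodeRecord(**r) for r in node_rows),
        (EdgeRecord(**r) for r in edge_rows),
        strict=strict,
    )


def write_graph(
    graph: PropertyGraph,
    nodes_table: str | Path,
    edges_table: str | Path,
    delimiter: str = "\t",
) -> None:
    """Write the graph back to the same two-table dialect ``load_graph`` reads.

    Round-trips exactly: nodes sorted by CUI, edges in insertion order.
    """
    with Path(nodes_table).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        w.writerow(NODE_COLUMNS)
        for cui in sorted(graph.nodes):
            rec = graph.nodes[cui]
            w.writerow((rec.cui, rec.node_type, rec.display_label))
    with Path(edges_table).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        w.writerow(EDGE_COLUMNS)
        for e in graph.edges:
            w.writerow((e.source_cui, e.target_cui, e.relation_type, e.provenance_sab))


def condense(graph: PropertyGraph, keep_types: set[str]) -> PropertyGraph:
    """Restrict the graph to nodes of the given types.

    This is the node-type subsetting step that turns a sprawling
    multi-ontology graph into the compact disease/compound/gene/ontology
    subgraph the labeling queries run against.  Edges survive only when
    both endpoints do.  Idempotent; an empty intersection with the graph's
    types yields an empty graph.
    """
    if not keep_types:
        raise ValueError("keep_types must be non-empty")
    kept = [rec for rec in graph.nodes.values() if rec.node_type in keep_types]
    kept_cuis = {rec.cui for rec in kept}
    kept_edges = [
        e
        for e in graph.edges
        if e.source_cui in kept_cuis and e.target_cui in kept_cuis
    ]
    return PropertyGraph.from_records(kept, kept_edges)


def neighbors(
    graph: PropertyGraph, cui: str, type_filter: str | None = None
) -> set[str]:
    """Adjacent CUIs of ``cui``, optionally restricted to one node type."""
    if cui not in graph.nodes:
        raise KeyError(f"unknown CUI {cui!r}")
    adj = graph.adjacency[cui]
    if type_filter is None:
        return set(adj)
    return {c for c in adj if graph.nodes[c].node_type == type_filter}


def to_graphml(graph: PropertyGraph, path: str | Path) -> None:
    """Export for visualization; requires :mod:`networkx`."""
    import networkx as nx

    g = nx.Graph()
    for cui, rec in graph.nodes.items():
        g.add_node(cui, node_type=rec.node_type, display_label=rec.display_label)
    for e in graph.edges:
        g.add_edge(e.source_cui, e.target_cui, relation_type=e.relation_type,
                   provenance_sab=e.provenance_sab)
    nx.write_graphml(g, str(path))
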
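"""Protein networks built from pairwise sequence-similarity hits or edge lists.

The central object is the protein similarity network (PSIN): an undirected,
unweighted simple graph in which two proteins are linked only if a sequence
similarity search launched from *each* of them retrieves the other (a
"bidirectional hit").  Similarity searches are not reciprocal, so the
directed hit relation must be intersected with its transpose.  A
protein-protein interaction (PPI) network is handled by the same container,
loaded from a plain edge list instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import networkx as nx

__all__ = [
    "SimilarityHit",
    "BlastParams",
    "ProteinNetwork",
    "NetworkSummary",
    "parse_blast_tabular",
    "build_psin",
    "load_edge_list",
    "load_node_list",
    "network_summary",
    "write_edge_list",
]


class ParseError(ValueError):
    """Raised for malformed input lines; carries the offending line number."""


@dataclass(frozen=True)
class SimilarityHit:
    """One directed query->subject similarity record with an expectation value."""

    query_id: str
    subject_id: str
    evalue: float

    def __post_init__(self) -> None:
        if not self.query_id or not self.subject_id:
            raise ValueError("query_id and subject_id must be non-empty")
        if self.evalue < 0:
            raise ValueError(f"evalue must be >= 0, got {self.evalue}")


@dataclass(frozen=True)
class BlastParams:
    """Provenance record of the sequence-comparison parameters.

    These describe how the upstream all-against-all PSI-BLAST search that
    produces the hit table is expected to have been run; this package
    consumes the tabular output and never executes the search itself.
    """

    gap_open_cost: int = 11
    gap_extend_cost: int = 1
    evalue_max: float = 1e-3
    inclusion_evalue: float = 1e-5
    max_iterations: int = 6
    matrix_name: str = "BLOSUM"

    def __post_init__(self) -> None:
        if self.gap_open_cost <= 0 or self.gap_extend_cost <= 0:
            raise ValueError("gap costs must be positive")
        if not (0 < self.evalue_max < 1 and 0 < self.inclusion_evalue < 1):
            raise ValueError("e-value thresholds must lie in (0, 1)")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class ProteinNetwork:
    """Undirected simple graph over protein identifiers.

    ``kind`` tags the network as a similarity network (``"psin"``) or an
    interaction network (``"ppi"``).  Isolated nodes are legitimate members:
    proteins with no bidirectional hit stay in the network as singletons.
    """

    kind: str = "psin"
    graph: nx.Graph = field(default_factory=nx.Graph)

    def __post_init__(self) -> None:
        self.kind = self.kind.lower()
        if self.kind not in ("psin", "ppi"):
            raise ValueError(f"kind must be 'psin' or 'ppi', got {self.kind!r}")

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset((u, v)) for u, v in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self.graph


@dataclass(frozen=True)
class NetworkSummary:
    n_nodes: int
    n_edges: int
    n_components: int
    mean_degree: float
    max_degree: int

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def parse_blast_tabular(
    stream: Iterable[str], evalue_max: float = 1e-3
) -> list[SimilarityHit]:
    """Parse BLAST tabular output (outfmt 6) into directed similarity hits.

    Standard 12-column format; columns 1, 2 and 11 are query id, subject id
    and e-value.  Lines starting with ``#`` are skipped.  Hits with e-value
    above ``evalue_max`` and self-hits are dropped; duplicate (query,
    subject) pairs (one row per iteration/HSP) keep the smallest e-value.
    """
    best: dict[tuple[str, str], float] = {}
    order: list[tuple[str, str]] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 11:
            raise ParseError(
                f"line {lineno}: expected >= 11 tab-separated fields, got {len(fields)}"
            )
        query, subject = fields[0], fields[1]
        try:
            evalue = float(fields[10])
        except ValueError as exc:
            raise ParseError(
                f"line {lineno}: cannot parse e-value field {fields[10]!r}"
            ) from exc
        if evalue > evalue_max or query == subject:
            continue
        key = (query, subject)
        if key not in best:
            best[key] = evalue
            order.append(key)
        elif evalue < best[key]:
            best[key] = evalue
    return [SimilarityHit(q, s, best[(q, s)]) for q, s in order]


def build_psin(
    hits: Iterable[SimilarityHit], nodes: Optional[Iterable[str]] = None
) -> ProteinNetwork:
    """Build the similarity network: edge {A,B} iff both A->B and B->A hit.

    ``nodes`` optionally supplies a node universe (e.g. the full proteome)
    so that proteins with no bidirectional hit are retained as singletons;
    otherwise the node set is derived from the hits alone.
    """
    directed: set[tuple[str, str]] = set()
    seen: set[str] = set()
    for hit in hits:
        directed.add((hit.query_id, hit.subject_id))
        seen.add(hit.query_id)
        seen.add(hit.subject_id)
    graph = nx.Graph()
    graph.add_nodes_from(seen)
    if nodes is not None:
        graph.add_nodes_from(nodes)
    for a, b in directed:
        if a < b and (b, a) in directed:
            graph.add_edge(a, b)
    return ProteinNetwork(kind="psin", graph=graph)


def load_edge_list(
    stream: Iterable[str],
    kind: str = "ppi",
    confidence_min: Optional[float] = None,
    nodes: Optional[Iterable[str]] = None,
) -> ProteinNetwork:
    """Load an undirected network from TSV lines ``idA<TAB>idB[<TAB>confidence]``.

    Rows with confidence below ``confidence_min`` are dropped; duplicate and
    reversed pairs collapse to one edge; self-loops are discarded.  Without a
    ``nodes`` universe the node set comes only from surviving rows.
    """
    graph = nx.Graph()
    if nodes is not None:
        graph.add_nodes_from(nodes)
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) not in (2, 3):
            raise ParseError(
                f"line {lineno}: expected 2 or 3 columns, got {len(fields)}"
            )
        a, b = fields[0], fields[1]
        if confidence_min is not None and len(fields) == 3:
            try:
                conf = float(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"line {lineno}: cannot parse confidence {fields[2]!r}"
                ) from exc
            if conf < confidence_min:
                continue
        if a == b:
            continue
        graph.add_edge(a, b)
    return ProteinNetwork(kind=kind, graph=graph)


def load_node_list(stream: Iterable[str]) -> set[str]:
    """Read a node universe: one protein id per line, blank lines ignored."""
    return {line.strip() for line in stream if line.strip()}


def network_summary(net: ProteinNetwork) -> NetworkSummary:
    """Node, edge and connected-component counts plus degree statistics."""
    g = net.graph
    n = g.number_of_nodes()
    degrees = [d for _, d in g.degree()]
    return NetworkSummary(
        n_nodes=n,
        n_edges=g.number_of_edges(),
        n_components=nx.number_connected_components(g) if n else 0,
        mean_degree=(2 * g.number_of_edges() / n) if n else 0.0,
        max_degree=max(degrees, default=0),
    )


def write_edge_list(net: ProteinNetwork, edge_path, node_path=None) -> None:
    """Write the network as an edge-list TSV plus an optional node-list file."""
    with open(edge_path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in net.graph.edges):
            fh.write(f"{u}\t{v}\n")
    if node_path is not None:
        with open(node_path, "w") as fh:
            for node in sorted(net.graph.nodes):
                fh.write(f"{node}\n")


def iter_lines(path) -> Iterator[str]:
    with open(path) as fh:
        yield from fh
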
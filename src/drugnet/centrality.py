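"""Node centralities on protein networks and the "danger zone" flags.

Four measures drive the analysis: degree, betweenness, closeness and Burt's
constraint.  Burt's constraint comes from social-network theory: it
quantifies how concentrated a node's connections are within one mutually
connected group.  With unweighted proportional tie strength
``p_ij = 1/deg(i)``::

    C(i) = sum_j ( p_ij + sum_q p_iq * p_qj )^2,   q in N(i) & N(j), q != i, j

Low constraint means the node brokers "structural holes" between otherwise
unconnected neighbourhoods — in a similarity network, a protein whose
domains recur across many families.  Targets of problematic drugs sit in a
high-degree / low-constraint regime, the "danger zone" for therapeutic
modulation.

Betweenness is unnormalised and counts each unordered pair once::

    B(v) = sum_{i != j, v not in {i, j}} s_ij(v) / s_ij

with ``s_ij`` the number of shortest i-j paths and ``s_ij(v)`` those through
``v``.  Closeness defaults to the inverse mean distance over reachable
nodes, which stays well defined on networks with many components.

Closeness and constraint are undefined (``NaN``) for isolated nodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import networkx as nx
import pandas as pd

from .network import ProteinNetwork

__all__ = [
    "CentralityRecord",
    "DangerZoneThresholds",
    "DangerZoneFlags",
    "degree",
    "betweenness",
    "closeness",
    "burts_constraint",
    "centrality_table",
    "danger_zone",
    "danger_zone_table",
]

CENTRALITY_COLUMNS = ["degree", "betweenness", "closeness", "burts_constraint"]


@dataclass(frozen=True)
class CentralityRecord:
    protein_id: str
    degree: int
    betweenness: float
    closeness: Optional[float]  # None when degree == 0
    burts_constraint: Optional[float]  # None when degree == 0


@dataclass(frozen=True)
class DangerZoneThresholds:
    """Degree/constraint cut-offs separating problematic-like targets.

    Defaults are the empirically optimal separation points: similarity
    network degree > 110 with constraint < 0.025, interaction network
    degree > 11 with constraint < 0.1.  All inequalities are strict.
    """

    psin_degree_min: float = 110.0
    psin_constraint_max: float = 0.025
    ppi_degree_min: float = 11.0
    ppi_constraint_max: float = 0.1


@dataclass(frozen=True)
class DangerZoneFlags:
    psin_flag: Optional[bool]
    ppi_flag: Optional[bool]
    combined_flag: Optional[bool]


def _require_node(net: ProteinNetwork, v: str) -> None:
    if v not in net.graph:
        raise KeyError(f"node {v!r} not in the {net.kind} network")


def degree(net: ProteinNetwork, v: str) -> int:
    _require_node(net, v)
    return net.graph.degree(v)


def betweenness(net: ProteinNetwork, v: str) -> float:
    _require_node(net, v)
    return nx.betweenness_centrality(net.graph, normalized=False)[v]


def closeness(net: ProteinNetwork, v: str, variant: str = "mean") -> Optional[float]:
    """Closeness of ``v``; ``None`` for an isolated node.

    ``variant="mean"`` (default): r / sum(d) over the r reachable nodes,
    i.e. the inverse mean shortest-path distance.  ``variant="total"``:
    1 / sum(d), the inverse total distance.
    """
    _require_node(net, v)
    if net.graph.degree(v) == 0:
        return None
    lengths = nx.single_source_shortest_path_length(net.graph, v)
    total = sum(lengths.values())
    r = len(lengths) - 1  # exclude v itself
    if variant == "mean":
        return r / total
    if variant == "total":
        return 1.0 / total
    raise ValueError(f"unknown closeness variant {variant!r}")


def burts_constraint(net: ProteinNetwork, v: str) -> Optional[float]:
    """Burt's constraint of ``v``; ``None`` for an isolated node."""
    _require_node(net, v)
    if net.graph.degree(v) == 0:
        return None
    return nx.constraint(net.graph, nodes=[v])[v]


def centrality_table(net: ProteinNetwork, closeness_variant: str = "mean") -> pd.DataFrame:
    """All four centralities for every node, indexed by protein id.

    Missing values (closeness/constraint of isolated nodes) are ``NaN``.
    Deterministic: rows are sorted by protein id.
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        return pd.DataFrame(columns=CENTRALITY_COLUMNS).rename_axis("protein_id")
    btw = nx.betweenness_centrality(g, normalized=False)
    non_isolated = [n for n, d in g.degree() if d > 0]
    constraint = nx.constraint(g.subgraph(non_isolated)) if non_isolated else {}
    rows = {}
    for n in g.nodes:
        deg = g.degree(n)
        if deg == 0:
            clo = math.nan
            con = math.nan
        else:
            clo = closeness(net, n, variant=closeness_variant)
            con = constraint[n]
        rows[n] = (deg, btw[n], clo, con)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=CENTRALITY_COLUMNS)
    df.index.name = "protein_id"
    return df.sort_index()


def _flag(record, degree_min: float, constraint_max: float) -> Optional[bool]:
    if record is None:
        return None
    deg = record["degree"] if isinstance(record, (dict, pd.Series)) else record.degree
    con = (
        record["burts_constraint"]
        if isinstance(record, (dict, pd.Series))
        else record.burts_constraint
    )
    if con is None or (isinstance(con, float) and math.isnan(con)):
        return False  # no constraint value -> cannot sit in the danger zone
    return bool(deg > degree_min and con < constraint_max)


def danger_zone(
    psin_rec=None,
    ppi_rec=None,
    thresholds: DangerZoneThresholds = DangerZoneThresholds(),
) -> DangerZoneFlags:
    """Flag a protein as problematic-like in either or both networks.

    Records may be :class:`CentralityRecord`, dict-like rows of a
    centrality table, or ``None`` when the protein is absent from that
    network (the corresponding flag is then missing).
    """
    psin_flag = _flag(psin_rec, thresholds.psin_degree_min, thresholds.psin_constraint_max)
    ppi_flag = _flag(ppi_rec, thresholds.ppi_degree_min, thresholds.ppi_constraint_max)
    combined = (psin_flag and ppi_flag) if (psin_flag is not None and ppi_flag is not None) else None
    return DangerZoneFlags(psin_flag=psin_flag, ppi_flag=ppi_flag, combined_flag=combined)


def danger_zone_table(
    psin_table: Optional[pd.DataFrame],
    ppi_table: Optional[pd.DataFrame],
    thresholds: DangerZoneThresholds = DangerZoneThresholds(),
) -> pd.DataFrame:
    """Danger-zone flags for every protein appearing in either table."""
    ids = set()
    if psin_table is not None:
        ids |= set(psin_table.index)
    if ppi_table is not None:
        ids |= set(ppi_table.index)
    rows = {}
    for pid in sorted(ids):
        psin_rec = psin_table.loc[pid] if psin_table is not None and pid in psin_table.index else None
        ppi_rec = ppi_table.loc[pid] if ppi_table is not None and pid in ppi_table.index else None
        flags = danger_zone(psin_rec, ppi_rec, thresholds)
        rows[pid] = (flags.psin_flag, flags.ppi_flag, flags.combined_flag)
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["psin_flag", "ppi_flag", "combined_flag"]
    )
    df.index.name = "protein_id"
    return df
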
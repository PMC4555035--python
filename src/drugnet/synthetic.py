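"""Synthetic generators emulating the statistical structure of the real data.

The real inputs — an all-against-all similarity search over the human
proteome, curated drug-target tables, an interaction database — cannot be
shipped, so this module generates stand-ins with the features the analysis
relies on:

* a similarity network built from preferential attachment, giving the
  heavy-tailed (power-law-like) degree distribution and several connected
  components observed in practice;
* a minority problematic class (~20 % of labelled drugs, mirroring the
  roughly 4:1 approved:problematic imbalance);
* problematic drugs preferentially targeting hubs (target probability
  proportional to degree^bias) while approved drugs draw targets from the
  sub-hub periphery;
* problematic drugs carrying mostly a single target, approved drugs
  several;
* optional label noise confined to configurable failure-reason groups, so
  ablation experiments have a planted mechanism to find.

Every generator is a pure function of its configuration, including the
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import networkx as nx
import numpy as np

from .drugs import APPROVED, PROBLEMATIC, DrugRecord
from .network import ProteinNetwork

__all__ = [
    "FAILURE_REASONS",
    "SimulationConfig",
    "generate_network",
    "generate_ppi",
    "generate_drugs",
    "generate_blast_fixture",
]

FAILURE_REASONS = [
    "withdrawn",
    "safety",
    "efficacy",
    "toxicity",
    "adverse-events",
    "pharmacokinetics",
    "formulation",
    "commercial",
    "clinical-hold",
    "regulatory",
]


@dataclass(frozen=True)
class SimulationConfig:
    n_proteins: int = 1000
    attachment_edges: int = 3  # preferential-attachment growth parameter
    n_components: int = 4
    n_approved: int = 400
    n_problematic: int = 100  # ~20% problematic, mirroring the 4:1 imbalance
    hub_quantile: float = 0.9  # approved drugs draw from below this degree quantile
    problematic_hub_bias: float = 2.0  # target prob ~ degree**bias
    approved_extra_targets_mean: float = 2.5  # targets = 1 + Poisson(mean)
    problematic_extra_targets_mean: float = 0.3  # mostly single-target
    label_noise: float = 0.0
    noise_reason: str = "withdrawn"  # failure reason carried by noisy problematic drugs
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_proteins, self.n_components, self.n_approved, self.n_problematic) < 1:
            raise ValueError("counts must be positive")
        if not (0 < self.hub_quantile <= 1):
            raise ValueError("hub_quantile must lie in (0, 1]")
        if not (0 <= self.label_noise < 1):
            raise ValueError("label_noise must lie in [0, 1)")
        if self.problematic_hub_bias < 0:
            raise ValueError("problematic_hub_bias must be >= 0")
        if self.noise_reason not in FAILURE_REASONS:
            raise ValueError(f"noise_reason must be one of {FAILURE_REASONS}")


def _component_sizes(n: int, k: int, m: int) -> list[int]:
    if n < k * (m + 1):
        raise ValueError(
            f"n_proteins={n} too small for {k} components with attachment_edges={m}"
        )
    base = n // k
    sizes = [base] * k
    sizes[0] += n - base * k
    return sizes


def generate_network(config: SimulationConfig) -> ProteinNetwork:
    """Union of independent preferential-attachment components.

    Heavy-tailed degree distribution within each component; node ids are
    ``P00000``-style, assigned component by component.
    """
    rng = np.random.default_rng(config.seed)
    sizes = _component_sizes(config.n_proteins, config.n_components, config.attachment_edges)
    graph = nx.Graph()
    offset = 0
    for size in sizes:
        comp = nx.barabasi_albert_graph(
            size, config.attachment_edges, seed=int(rng.integers(0, 2**31 - 1))
        )
        mapping = {i: f"P{offset + i:05d}" for i in comp.nodes}
        graph.update(nx.relabel_nodes(comp, mapping))
        offset += size
    return ProteinNetwork(kind="psin", graph=graph)


def generate_ppi(
    psin: ProteinNetwork, config: SimulationConfig, node_fraction: float = 0.6
) -> ProteinNetwork:
    """Interaction network over a random subset of the same proteins.

    Independent preferential-attachment topology (interaction and
    similarity structure are distinct in reality), sharing identifiers
    with the similarity network so drugs can be restricted to either.
    """
    rng = np.random.default_rng(config.seed + 1)
    nodes = sorted(psin.nodes)
    n = max(int(node_fraction * len(nodes)), config.attachment_edges + 2)
    chosen = list(rng.choice(nodes, size=n, replace=False))
    comp = nx.barabasi_albert_graph(
        n, config.attachment_edges, seed=int(rng.integers(0, 2**31 - 1))
    )
    mapping = {i: chosen[i] for i in comp.nodes}
    return ProteinNetwork(kind="ppi", graph=nx.relabel_nodes(comp, mapping))


def _draw_targets(
    rng: np.random.Generator, pool: np.ndarray, probs: Optional[np.ndarray], k: int
) -> frozenset[str]:
    k = min(k, len(pool))
    idx = rng.choice(len(pool), size=k, replace=False, p=probs)
    return frozenset(pool[idx])


def generate_drugs(net: ProteinNetwork, config: SimulationConfig) -> list[DrugRecord]:
    """Drug-target records with class-dependent target placement.

    Problematic drugs sample targets with probability proportional to
    ``degree**problematic_hub_bias``; approved drugs sample uniformly from
    nodes below the ``hub_quantile`` degree quantile.  Target counts are
    ``1 + Poisson`` with class-specific means.  A ``label_noise`` fraction
    of each class draws its targets from the *other* class's distribution
    (labels and class counts stay fixed); noisy problematic drugs carry
    ``noise_reason`` as their failure reason, genuine problematic drugs
    carry one of the other reasons.
    """
    rng = np.random.default_rng(config.seed + 2)
    nodes = np.array(sorted(net.nodes))
    degrees = np.array([net.graph.degree(n) for n in nodes], dtype=float)

    threshold = np.quantile(degrees, config.hub_quantile)
    periphery_mask = degrees <= threshold
    periphery = nodes[periphery_mask]

    hub_w = degrees ** config.problematic_hub_bias
    if hub_w.sum() == 0:
        hub_w = np.ones_like(hub_w)
    hub_p = hub_w / hub_w.sum()

    def hub_targets(k: int) -> frozenset[str]:
        return _draw_targets(rng, nodes, hub_p, k)

    def periphery_targets(k: int) -> frozenset[str]:
        return _draw_targets(rng, periphery, None, k)

    records: list[DrugRecord] = []
    n_noisy_app = round(config.label_noise * config.n_approved)
    n_noisy_prob = round(config.label_noise * config.n_problematic)
    other_reasons = [r for r in FAILURE_REASONS if r != config.noise_reason]

    for i in range(config.n_approved):
        k = 1 + int(rng.poisson(config.approved_extra_targets_mean))
        noisy = i < n_noisy_app
        targets = hub_targets(k) if noisy else periphery_targets(k)
        records.append(
            DrugRecord(
                drug_id=f"APP{i:04d}", raw_status="approved",
                label=APPROVED, targets=targets,
            )
        )
    for i in range(config.n_problematic):
        k = 1 + int(rng.poisson(config.problematic_extra_targets_mean))
        noisy = i < n_noisy_prob
        targets = periphery_targets(k) if noisy else hub_targets(k)
        reason = config.noise_reason if noisy else other_reasons[i % len(other_reasons)]
        records.append(
            DrugRecord(
                drug_id=f"PRB{i:04d}",
                raw_status="withdrawn" if reason == "withdrawn" else "discontinued",
                label=PROBLEMATIC, targets=targets, failure_reason=reason,
            )
        )
    return records


def generate_blast_fixture(
    net: ProteinNetwork,
    seed: int = 0,
    n_decoys: int = 50,
    n_supra: int = 50,
    evalue_max: float = 1e-3,
) -> str:
    """BLAST-tabular text whose bidirectional hits reconstruct ``net`` exactly.

    Every edge is emitted in both directions with a passing e-value.
    ``n_decoys`` one-directional rows and ``n_supra`` above-threshold rows
    over non-edges are added; neither class of row can create an edge
    under the bidirectional rule with e-value filtering.
    """
    rng = np.random.default_rng(seed)
    nodes = sorted(net.nodes)
    edge_set = {tuple(sorted(e)) for e in net.graph.edges}

    def row(q: str, s: str, evalue: float) -> str:
        ident = rng.uniform(30, 99)
        length = rng.integers(50, 400)
        bits = max(20.0, -10 * math.log10(max(evalue, 1e-180)))
        return (
            f"{q}\t{s}\t{ident:.2f}\t{length}\t{rng.integers(0, 30)}\t{rng.integers(0, 5)}"
            f"\t1\t{length}\t1\t{length}\t{evalue:.2e}\t{bits:.1f}"
        )

    def passing_evalue() -> float:
        return 10.0 ** (-rng.uniform(-math.log10(evalue_max) + 0.1, 30))

    lines: list[str] = ["# synthetic all-against-all similarity hits (outfmt 6)"]
    for a, b in sorted(edge_set):
        lines.append(row(a, b, passing_evalue()))
        lines.append(row(b, a, passing_evalue()))

    def sample_non_edge() -> tuple[str, str]:
        while True:
            a, b = rng.choice(nodes, size=2, replace=False)
            key = tuple(sorted((a, b)))
            if key not in edge_set:
                return key

    decoy_pairs: set[tuple[str, str]] = set()
    while len(decoy_pairs) < min(n_decoys, len(nodes) * (len(nodes) - 1) // 4):
        decoy_pairs.add(sample_non_edge())
    for a, b in sorted(decoy_pairs):
        lines.append(row(a, b, passing_evalue()))  # one direction only

    for _ in range(n_supra):
        a, b = sample_non_edge()
        lines.append(row(a, b, float(rng.uniform(evalue_max * 10, 1.0))))
    return "\n".join(lines) + "\n"
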
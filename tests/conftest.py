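"""Shared fixtures: small hand-built graphs and synthetic study datasets."""

import networkx as nx
import numpy as np
import pytest

from drugnet.centrality import centrality_table
from drugnet.features import build_feature_matrix
from drugnet.network import ProteinNetwork
from drugnet.synthetic import SimulationConfig, generate_drugs, generate_network


def make_net(edges, nodes=(), kind="psin"):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return ProteinNetwork(kind=kind, graph=g)


@pytest.fixture
def triangle():
    return make_net([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def path3():
    return make_net([("A", "B"), ("B", "C")])


def random_graph(n, p, rng):
    """Erdos-Renyi graph over string node ids."""
    g = nx.Graph()
    names = [f"N{i}" for i in range(n)]
    g.add_nodes_from(names)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(names[i], names[j])
    return ProteinNetwork(kind="psin", graph=g)


# ---------------------------------------------------------------------------
# Study-condition datasets (session scope: shared by pipeline-level tests)


@pytest.fixture(scope="session")
def signal_study():
    """Planted-signal dataset at the study scale.

    Scale-free similarity network over 1000 proteins, 400 approved + 100
    problematic drugs, problematic targets hub-biased (bias 2), no label
    noise.  Returns (drugs, centrality_table, raw_feature_matrix).
    """
    cfg = SimulationConfig(seed=11)
    net = generate_network(cfg)
    table = centrality_table(net)
    drugs = generate_drugs(net, cfg)
    raw = build_feature_matrix(drugs, table)
    return drugs, table, raw


@pytest.fixture(scope="session")
def noisy_study():
    """Dataset with label noise planted entirely in the 'withdrawn' group."""
    cfg = SimulationConfig(seed=13, label_noise=0.3, noise_reason="withdrawn")
    net = generate_network(cfg)
    table = centrality_table(net)
    drugs = generate_drugs(net, cfg)
    raw = build_feature_matrix(drugs, table)
    return drugs, table, raw


@pytest.fixture(scope="session")
def null_study():
    """No-signal dataset: zero hub bias, whole-network target pool."""
    cfg = SimulationConfig(seed=17, problematic_hub_bias=0.0, hub_quantile=1.0)
    net = generate_network(cfg)
    table = centrality_table(net)
    drugs = generate_drugs(net, cfg)
    raw = build_feature_matrix(drugs, table)
    return drugs, table, raw


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
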
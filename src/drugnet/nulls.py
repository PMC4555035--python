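"""Randomisation null models validating the classification pipeline.

Three permutation tests probe whether the classifiers exploit genuine
network structure rather than confounders (targets-per-drug counts,
class imbalance):

1. shuffle class labels and target assignments jointly, preserving class
   proportions and per-drug target counts — performance should fall to
   chance (AUC ~ 0.5);
2. a paired design: for each evaluation round the *same* drug-id
   train/test partition is applied to the standard dataset and to a panel
   of randomised datasets, yielding a null AUC distribution and an
   exceedance fraction;
3. permute the protein identifiers of the network itself, preserving its
   entire topology while destroying the identity of every node.

A Fisher exact test asks whether drugs target network-adjacent protein
pairs more often than a degree-preserving random draw would.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import ClassifierSpec, EvaluationReport, auc, default_specs, predict_problematic_prob, train, _prepare_split
from .drugs import DrugRecord
from .features import FeatureMatrix, build_feature_matrix
from .imbalance import PreprocessConfig
from .network import ProteinNetwork

__all__ = [
    "NullDistribution",
    "shuffle_labels_and_targets",
    "shuffle_network_labels",
    "paired_null_eval",
    "neighbor_targeting_test",
    "fisher_exact_p",
]


@dataclass
class NullDistribution:
    auc_values: list[float]  # all null AUCs (n_rounds * n_random)
    standard_aucs: list[float]
    n_random: int
    empirical_exceedance: float  # fraction of comparisons where standard beats null


def shuffle_labels_and_targets(
    drugs: Sequence[DrugRecord],
    seed: int = 0,
    shuffle_labels: bool = True,
    shuffle_targets: bool = True,
) -> list[DrugRecord]:
    """Permute class labels across drugs and randomise target assignments.

    Class counts are preserved exactly (labels are a permutation); each
    drug's new target set is a uniform sample of the same size from the
    pooled target universe.  Status and failure reason travel with the
    label.
    """
    drugs = list(drugs)
    rng = random.Random(seed)
    out = drugs
    if shuffle_labels:
        tags = [(d.label, d.raw_status, d.failure_reason) for d in drugs]
        rng.shuffle(tags)
        out = [
            replace(d, label=t[0], raw_status=t[1], failure_reason=t[2])
            for d, t in zip(out, tags)
        ]
    if shuffle_targets:
        universe = sorted(set().union(*(d.targets for d in drugs)))
        out = [
            replace(d, targets=frozenset(rng.sample(universe, len(d.targets))), ic50_nM=None)
            for d in out
        ]
    return out


def shuffle_network_labels(net: ProteinNetwork, seed: int = 0) -> ProteinNetwork:
    """Permute node identifiers over the same graph.

    Every topological invariant (degree sequence, components, triangles)
    is preserved exactly; only which protein occupies which position
    changes.
    """
    import networkx as nx

    rng = random.Random(seed)
    nodes = sorted(net.graph.nodes)
    permuted = nodes[:]
    rng.shuffle(permuted)
    mapping = dict(zip(nodes, permuted))
    return ProteinNetwork(kind=net.kind, graph=nx.relabel_nodes(net.graph, mapping, copy=True))


def _eval_partition(
    drugs_by_id: dict[str, DrugRecord],
    raw: FeatureMatrix,
    train_ids: Sequence[str],
    test_ids: Sequence[str],
    specs: Sequence[ClassifierSpec],
    config: PreprocessConfig,
) -> float:
    """Ensemble AUC for a fixed drug-id partition (with target-set hygiene)."""
    test_sets = {drugs_by_id[i].targets for i in test_ids}
    kept_train = [i for i in train_ids if drugs_by_id[i].targets not in test_sets]
    train_m = FeatureMatrix(raw.values.loc[kept_train], raw.labels.loc[kept_train])
    test_m = FeatureMatrix(raw.values.loc[list(test_ids)], raw.labels.loc[list(test_ids)])
    train_p, test_p, _ = _prepare_split(train_m, test_m, config)
    y_test = test_p.labels.to_numpy()
    probs = [
        predict_problematic_prob(train(s, train_p), test_p) for s in specs
    ]
    return auc(y_test, np.mean(probs, axis=0))


def paired_null_eval(
    drugs: Sequence[DrugRecord],
    psin_table: pd.DataFrame,
    ppi_table: Optional[pd.DataFrame] = None,
    n_random: int = 40,
    n_rounds: int = 5,
    specs: Optional[Sequence[ClassifierSpec]] = None,
    config: Optional[PreprocessConfig] = None,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> NullDistribution:
    """Paired comparison of the standard dataset against randomised panels.

    ``n_random`` randomised datasets are generated once (labels and
    targets shuffled, class proportions kept).  Per round, one stratified
    split of the standard dataset fixes the drug-id partition; the same
    partition is applied to every randomised dataset.  The exceedance is
    the fraction of (round, null) comparisons where the standard AUC beats
    the null AUC (ties count half).
    """
    from .drugs import split_train_test

    drugs = list(drugs)
    if specs is None:
        specs = default_specs(seed)
    if config is None:
        config = PreprocessConfig(seed=seed)
    rng = np.random.default_rng(seed)
    null_sets = [
        shuffle_labels_and_targets(drugs, seed=int(rng.integers(0, 2**31 - 1)))
        for _ in range(n_random)
    ]
    raw_std = build_feature_matrix(drugs, psin_table, ppi_table)
    raw_nulls = [build_feature_matrix(ns, psin_table, ppi_table) for ns in null_sets]
    by_id_std = {d.drug_id: d for d in drugs}
    by_id_nulls = [{d.drug_id: d for d in ns} for ns in null_sets]

    standard_aucs: list[float] = []
    null_aucs: list[float] = []
    wins = 0.0
    comparisons = 0
    for _ in range(n_rounds):
        round_seed = int(rng.integers(0, 2**31 - 1))
        tr, te, _ = split_train_test(drugs, train_fraction, round_seed)
        train_ids = [d.drug_id for d in tr]
        test_ids = [d.drug_id for d in te]
        cfg = PreprocessConfig(**{**config.__dict__, "seed": round_seed})
        std_auc = _eval_partition(by_id_std, raw_std, train_ids, test_ids, specs, cfg)
        standard_aucs.append(std_auc)
        for by_id, raw_n in zip(by_id_nulls, raw_nulls):
            n_auc = _eval_partition(by_id, raw_n, train_ids, test_ids, specs, cfg)
            null_aucs.append(n_auc)
            wins += 1.0 if std_auc > n_auc else (0.5 if std_auc == n_auc else 0.0)
            comparisons += 1
    return NullDistribution(
        auc_values=null_aucs,
        standard_aucs=standard_aucs,
        n_random=n_random,
        empirical_exceedance=wins / comparisons,
    )


def fisher_exact_p(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 contingency table."""
    return float(stats.fisher_exact(np.asarray(table), alternative="two-sided")[1])


def neighbor_targeting_test(
    records: Sequence[DrugRecord], psin: ProteinNetwork, seed: int = 0
) -> tuple[np.ndarray, float]:
    """Do drugs target similarity-network-adjacent protein pairs?

    For every drug with >= 2 targets, check whether any pair of its
    targets is adjacent in the network.  The null column repeats the count
    after replacing each target with a uniform draw from its degree bin
    (powers-of-two bins), preserving the degree profile of the target set.
    Returns the 2x2 table ``[[obs_adjacent, obs_not], [null_adjacent,
    null_not]]`` and the two-sided Fisher exact p-value.
    """
    multi = [r for r in records if len(r.targets & psin.nodes) >= 2]
    if not multi:
        raise ValueError("no drug has >= 2 targets in the network")
    rng = random.Random(seed)
    g = psin.graph
    bins: dict[int, list[str]] = {}
    for node in g.nodes:
        deg = g.degree(node)
        key = deg.bit_length()  # log2 degree bin; 0 for isolated nodes
        bins.setdefault(key, []).append(node)
    for key in bins:
        bins[key].sort()

    def any_adjacent(targets: Sequence[str]) -> bool:
        targets = list(targets)
        for i, a in enumerate(targets):
            for b in targets[i + 1:]:
                if g.has_edge(a, b):
                    return True
        return False

    obs_yes = obs_no = null_yes = null_no = 0
    for rec in multi:
        targets = sorted(rec.targets & psin.nodes)
        if any_adjacent(targets):
            obs_yes += 1
        else:
            obs_no += 1
        random_targets = [
            rng.choice(bins[g.degree(t).bit_length()]) for t in targets
        ]
        if any_adjacent(random_targets):
            null_yes += 1
        else:
            null_no += 1
    table = np.array([[obs_yes, obs_no], [null_yes, null_no]])
    return table, fisher_exact_p(table)
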
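"""Heterogeneous classifier ensemble and the Rejection Score.

Three probabilistic classifiers built on different principles — a
distance-weighted instance-based learner, a single-hidden-layer
feed-forward network, and a rotation ensemble of decision trees — are
trained on the preprocessed drug features.  Each outputs the probability
that a drug belongs to the problematic class; their arithmetic mean is the
drug's Rejection Score (RS): near 0 means safe-like, near 1 means
problematic-like.  Evaluation is by repeated stratified 70/30 hold-out,
scored with the area under the ROC curve (problematic = positive class).

The classifier registry is pluggable: any sklearn-style estimator factory
can be registered under a family name and evaluated alongside the
defaults.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier

from .drugs import DrugRecord, LabeledDataset, PROBLEMATIC, remove_failure_group, split_train_test
from .features import FeatureMatrix, impute_missing, scale_unit
from .imbalance import PreprocessConfig, preprocess

__all__ = [
    "ClassifierSpec",
    "RejectionScore",
    "EvaluationReport",
    "RotationForestClassifier",
    "default_specs",
    "register_family",
    "train",
    "predict_problematic_prob",
    "rejection_score",
    "auc",
    "repeated_holdout",
    "ablate_failure_reasons",
    "score_candidates",
    "rs_summary",
]


# ---------------------------------------------------------------------------
# Rotation ensemble


class RotationForestClassifier(BaseEstimator, ClassifierMixin):
    """Ensemble of decision trees, each trained on a rotated feature space.

    For every tree the features are randomly partitioned into small
    subsets; each subset is rotated onto the principal axes of a bootstrap
    sample, and the per-subset rotations are assembled into a
    block-diagonal rotation of the full space.  Rotating differently per
    tree decorrelates the trees while keeping each one trained on all the
    information in the data.
    """

    def __init__(self, n_estimators: int = 10, subset_size: int = 2,
                 random_state: int = 0):
        self.n_estimators = n_estimators
        self.subset_size = subset_size
        self.random_state = random_state

    def _rotation(self, X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        n, p = X.shape
        perm = rng.permutation(p)
        R = np.zeros((p, p))
        for start in range(0, p, self.subset_size):
            idx = perm[start:start + self.subset_size]
            boot = rng.integers(0, n, size=max(len(idx) + 1, (3 * n) // 4))
            sub = X[boot][:, idx]
            sub = sub - sub.mean(axis=0)
            # principal axes of the bootstrap sample via SVD
            _, _, vt = np.linalg.svd(sub, full_matrices=False)
            axes = np.eye(len(idx))
            axes[: vt.shape[0], :] = vt
            R[np.ix_(idx, idx)] = axes.T
        return R

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        rng = np.random.default_rng(self.random_state)
        self.rotations_ = []
        self.trees_ = []
        for _ in range(self.n_estimators):
            R = self._rotation(X, rng)
            tree = DecisionTreeClassifier(
                random_state=int(rng.integers(0, 2**31 - 1))
            )
            tree.fit(X @ R, y_enc)
            self.rotations_.append(R)
            self.trees_.append(tree)
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        probs = np.zeros((len(X), len(self.classes_)))
        for R, tree in zip(self.rotations_, self.trees_):
            p = tree.predict_proba(X @ R)
            probs[:, tree.classes_] += p
        return probs / self.n_estimators

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


# ---------------------------------------------------------------------------
# Registry and specs


@dataclass(frozen=True)
class ClassifierSpec:
    family: str
    hyperparameters: tuple = ()  # sorted (key, value) pairs
    seed: int = 0

    @classmethod
    def make(cls, family: str, seed: int = 0, **hyper) -> "ClassifierSpec":
        return cls(family=family, hyperparameters=tuple(sorted(hyper.items())), seed=seed)

    @property
    def hyper(self) -> dict:
        return dict(self.hyperparameters)


def _make_instance_based(hyper: dict, seed: int):
    return KNeighborsClassifier(
        n_neighbors=hyper.get("n_neighbors", 5), weights="distance"
    )


def _make_neural_net(hyper: dict, seed: int):
    return MLPClassifier(
        hidden_layer_sizes=hyper.get("hidden_layer_sizes", (12,)),
        max_iter=hyper.get("max_iter", 400),
        tol=hyper.get("tol", 1e-3),
        random_state=seed,
    )


def _make_rotation_ensemble(hyper: dict, seed: int):
    return RotationForestClassifier(
        n_estimators=hyper.get("n_estimators", 10),
        subset_size=hyper.get("subset_size", 2),
        random_state=seed,
    )


_REGISTRY: dict[str, Callable[[dict, int], object]] = {
    "instance_based": _make_instance_based,
    "neural_net": _make_neural_net,
    "rotation_ensemble": _make_rotation_ensemble,
}


def register_family(name: str, factory: Callable[[dict, int], object]) -> None:
    """Register an estimator factory ``factory(hyperparameters, seed)``."""
    _REGISTRY[name] = factory


def default_specs(seed: int = 0) -> list[ClassifierSpec]:
    """The three default heterogeneous classifiers."""
    return [
        ClassifierSpec.make("instance_based", seed=seed),
        ClassifierSpec.make("neural_net", seed=seed),
        ClassifierSpec.make("rotation_ensemble", seed=seed),
    ]


class TrainingError(ValueError):
    pass


@dataclass
class _FittedModel:
    spec: ClassifierSpec
    estimator: object
    feature_names: list[str]


def train(spec: ClassifierSpec, matrix: FeatureMatrix) -> _FittedModel:
    """Fit one classifier on a preprocessed feature matrix."""
    if spec.family not in _REGISTRY:
        raise TrainingError(
            f"unknown classifier family {spec.family!r}; registered: {sorted(_REGISTRY)}"
        )
    y = matrix.labels.to_numpy()
    if len(np.unique(y)) < 2:
        raise TrainingError("training set contains a single class")
    est = _REGISTRY[spec.family](spec.hyper, spec.seed)
    X = matrix.values.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X, y == PROBLEMATIC)
    return _FittedModel(spec, est, list(matrix.values.columns))


def predict_problematic_prob(model: _FittedModel, matrix: FeatureMatrix) -> np.ndarray:
    """Probability of the problematic class for every row of ``matrix``."""
    if list(matrix.values.columns) != model.feature_names:
        raise ValueError(
            f"feature mismatch: model expects {model.feature_names}, "
            f"got {list(matrix.values.columns)}"
        )
    X = matrix.values.to_numpy(dtype=float)
    proba = model.estimator.predict_proba(X)
    pos = list(model.estimator.classes_).index(True)
    return np.clip(proba[:, pos], 0.0, 1.0)


# ---------------------------------------------------------------------------
# Rejection Score and AUC


@dataclass(frozen=True)
class RejectionScore:
    drug_id: str
    score: float
    component_probs: tuple[float, ...]


def rejection_score(probs: Sequence[float], drug_id: str = "") -> RejectionScore:
    """Mean of the three per-classifier problematic probabilities."""
    if len(probs) != 3:
        raise ValueError(f"expected 3 component probabilities, got {len(probs)}")
    for p in probs:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"probability {p} outside [0, 1]")
    return RejectionScore(drug_id=drug_id, score=float(np.mean(probs)),
                          component_probs=tuple(float(p) for p in probs))


def auc(labels: Sequence, scores: Sequence[float], positive=PROBLEMATIC) -> float:
    """Area under the ROC curve by the rank (Mann-Whitney) formulation.

    Ties contribute 1/2.  The problematic class is positive by default.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == positive]
    neg = scores[labels != positive]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUC requires both classes present")
    greater = (pos[:, None] > neg[None, :]).sum()
    equal = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * equal) / (len(pos) * len(neg)))


# ---------------------------------------------------------------------------
# Evaluation


@dataclass
class EvaluationReport:
    auc_values: list[float]  # ensemble AUC per repeat
    per_spec_auc: dict[str, list[float]]
    n_repeats: int
    dataset_variant: str = "standard"
    seed: int = 0
    preprocess_reports: list[dict] = field(default_factory=list)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.auc_values))


def _prepare_split(
    train_m: FeatureMatrix,
    test_m: FeatureMatrix,
    config: PreprocessConfig,
) -> tuple[FeatureMatrix, FeatureMatrix, dict]:
    """Impute each side separately, scale on training bounds, rebalance train."""
    train_m = impute_missing(train_m)
    test_m = impute_missing(test_m)
    train_m, (test_m,) = scale_unit(train_m, [test_m])
    train_m, report = preprocess(train_m, config)
    return train_m, test_m, report


def _subset(raw: FeatureMatrix, drugs: Sequence[DrugRecord]) -> FeatureMatrix:
    ids = [d.drug_id for d in drugs]
    return FeatureMatrix(raw.values.loc[ids], raw.labels.loc[ids])


def repeated_holdout(
    drugs: Sequence[DrugRecord],
    raw: FeatureMatrix,
    specs: Optional[Sequence[ClassifierSpec]] = None,
    n_repeats: int = 100,
    train_fraction: float = 0.7,
    config: Optional[PreprocessConfig] = None,
    seed: int = 0,
    dataset_variant: str = "standard",
) -> EvaluationReport:
    """Repeated stratified hold-out evaluation of the ensemble.

    Per repeat: split the drugs 70/30 with target-set hygiene, impute and
    scale, rebalance the training split, train every spec, score the test
    drugs, and record per-spec and ensemble (mean-probability) AUC.
    """
    if specs is None:
        specs = default_specs(seed)
    if config is None:
        config = PreprocessConfig(seed=seed)
    rng = np.random.default_rng(seed)
    ensemble_aucs: list[float] = []
    per_spec: dict[str, list[float]] = {s.family: [] for s in specs}
    prep_reports: list[dict] = []
    for rep in range(n_repeats):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        train_drugs, test_drugs, _ = split_train_test(list(drugs), train_fraction, rep_seed)
        train_m = _subset(raw, train_drugs)
        test_m = _subset(raw, test_drugs)
        rep_config = PreprocessConfig(**{**config.__dict__, "seed": rep_seed})
        train_p, test_p, report = _prepare_split(train_m, test_m, rep_config)
        prep_reports.append(report)
        y_test = test_p.labels.to_numpy()
        probs = []
        for spec in specs:
            spec_r = ClassifierSpec(spec.family, spec.hyperparameters, rep_seed)
            model = train(spec_r, train_p)
            p = predict_problematic_prob(model, test_p)
            probs.append(p)
            per_spec[spec.family].append(auc(y_test, p))
        ensemble_aucs.append(auc(y_test, np.mean(probs, axis=0)))
    return EvaluationReport(
        auc_values=ensemble_aucs,
        per_spec_auc=per_spec,
        n_repeats=n_repeats,
        dataset_variant=dataset_variant,
        seed=seed,
        preprocess_reports=prep_reports,
    )


def ablate_failure_reasons(
    drugs: Sequence[DrugRecord],
    raw: FeatureMatrix,
    specs: Optional[Sequence[ClassifierSpec]] = None,
    n_repeats: int = 100,
    config: Optional[PreprocessConfig] = None,
    seed: int = 0,
) -> dict[str, EvaluationReport]:
    """Re-evaluate after removing each failure-reason group in turn.

    Returns one report per observed failure reason, enabling the
    comparison of which group of problematic drugs most confounds the
    classification.
    """
    reasons = sorted(
        {d.failure_reason for d in drugs if d.label == PROBLEMATIC and d.failure_reason}
    )
    out: dict[str, EvaluationReport] = {}
    for reason in reasons:
        subset = remove_failure_group(list(drugs), reason).drugs
        out[reason] = repeated_holdout(
            subset, raw, specs, n_repeats, config=config, seed=seed,
            dataset_variant=f"ablate:{reason}",
        )
    return out


def score_candidates(
    reference: Sequence[DrugRecord],
    candidates: Sequence[DrugRecord],
    raw_reference: FeatureMatrix,
    raw_candidates: FeatureMatrix,
    specs: Optional[Sequence[ClassifierSpec]] = None,
    config: Optional[PreprocessConfig] = None,
    seed: int = 0,
    drop_withdrawn: bool = True,
) -> list[RejectionScore]:
    """Leave-one-drug-out Rejection Scores for candidate drugs.

    For each candidate, the training set is the reference dataset minus
    every drug with the candidate's exact target set (and, by default,
    minus the "withdrawn" failure group, which confounds classification
    when present).  The candidate's missing features are filled with the
    training means and scaled with the training bounds.
    """
    if specs is None:
        specs = default_specs(seed)
    if config is None:
        config = PreprocessConfig(seed=seed)
    reference = list(reference)
    if drop_withdrawn and any(
        d.failure_reason == "withdrawn" for d in reference if d.label == PROBLEMATIC
    ):
        reference = remove_failure_group(reference, "withdrawn").drugs
    scores: list[RejectionScore] = []
    for cand in candidates:
        train_drugs = [d for d in reference if d.targets != cand.targets]
        train_m = impute_missing(_subset(raw_reference, train_drugs))
        cand_vals = raw_candidates.values.loc[[cand.drug_id]]
        cand_vals = cand_vals.fillna(train_m.imputation_means)
        cand_m = FeatureMatrix(cand_vals, raw_candidates.labels.loc[[cand.drug_id]])
        train_s, (cand_s,) = scale_unit(train_m, [cand_m])
        train_p, _ = preprocess(train_s, config)
        probs = []
        for spec in specs:
            model = train(spec, train_p)
            probs.append(float(predict_problematic_prob(model, cand_s)[0]))
        scores.append(rejection_score(probs, drug_id=cand.drug_id))
    return scores


def rs_summary(
    scores: Sequence[RejectionScore],
    labels: dict[str, str],
    cutoffs: Sequence[float] = (0.0, 0.02, 0.1, 0.25, 0.5, 0.75, 0.9, 0.95),
) -> pd.DataFrame:
    """Percentage of drugs of each class with RS >= cutoff.

    Rows are cutoffs (ascending); columns are class labels; every column is
    non-increasing down the rows.
    """
    cutoffs = list(cutoffs)
    if cutoffs != sorted(cutoffs):
        raise ValueError("cutoffs must be sorted ascending")
    by_class: dict[str, list[float]] = {}
    for s in scores:
        by_class.setdefault(labels[s.drug_id], []).append(s.score)
    for k, v in by_class.items():
        if not v:
            raise ValueError(f"class {k!r} has no drugs")
    data = {
        k: [100.0 * sum(s >= c for s in v) / len(v) for c in cutoffs]
        for k, v in sorted(by_class.items())
    }
    return pd.DataFrame(data, index=pd.Index(cutoffs, name="rs_cutoff"))
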
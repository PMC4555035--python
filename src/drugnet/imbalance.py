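"""Class-imbalance correction for the training set.

Labelled drug data are heavily skewed toward the approved class (roughly
4:1), and the two classes overlap in feature space.  The training set is
therefore rebalanced and cleaned by a four-step cascade, applied to the
training split only:

1. mean-impute missing features (handled upstream, see :mod:`.features`);
2. SMOTE: oversample the minority (problematic) class by interpolating
   between each minority point and one of its k nearest minority
   neighbours (default 500 %, k = 8);
3. remove Tomek links — pairs of opposite-class mutual nearest neighbours —
   and instances sitting on the class border (nearest neighbour of several
   opposite-class instances);
4. drop training instances a throwaway multilayer-perceptron filter,
   fitted on the training set itself, misclassifies.

Everything is seeded and deterministic; only SMOTE and the filter network
consume randomness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPClassifier

from .features import FeatureMatrix

__all__ = [
    "PreprocessConfig",
    "smote",
    "tomek_links",
    "remove_tomek",
    "remove_border",
    "remove_misclassified",
    "preprocess",
]


@dataclass
class PreprocessConfig:
    smote_percent: int = 500
    smote_k: int = 8
    border_threshold: int = 2
    smote_enabled: bool = True
    tomek_enabled: bool = True
    border_enabled: bool = True
    misclassified_enabled: bool = True
    tomek_remove_both: bool = True  # Batista-style removal of both link members
    strict_filter: bool = False  # hard error when the filter model fails to fit
    seed: int = 0

    def __post_init__(self) -> None:
        if self.smote_percent % 100 != 0:
            raise ValueError("smote_percent must be a multiple of 100")
        if self.smote_k < 1:
            raise ValueError("smote_k must be >= 1")
        if self.border_threshold < 1:
            raise ValueError("border_threshold must be >= 1")


def _minority_label(labels: pd.Series) -> str:
    counts = labels.value_counts()
    if "problematic" in counts.index and counts["problematic"] == counts.min():
        return "problematic"
    return counts.idxmin()


def smote(
    minority: np.ndarray, percent: int = 500, k: int = 8, seed: int = 0
) -> np.ndarray:
    """Synthetic minority oversampling.

    Generates ``(percent/100) * n`` synthetic points; each is
    ``x + u * (nn - x)`` for a uniformly chosen member ``nn`` of ``x``'s k
    nearest minority neighbours (Euclidean) and ``u ~ Uniform(0, 1)``.
    """
    minority = np.asarray(minority, dtype=float)
    n = len(minority)
    if n <= k:
        raise ValueError(f"SMOTE needs more than k={k} minority instances, got {n}")
    rng = np.random.default_rng(seed)
    from sklearn.neighbors import NearestNeighbors

    nn = NearestNeighbors(n_neighbors=k + 1).fit(minority)
    _, idx = nn.kneighbors(minority)  # column 0 is the point itself
    n_synth = (percent // 100) * n
    base = np.tile(np.arange(n), percent // 100)[:n_synth]
    chosen = idx[base, rng.integers(1, k + 1, size=n_synth)]
    u = rng.uniform(0.0, 1.0, size=(n_synth, 1))
    return minority[base] + u * (minority[chosen] - minority[base])


def tomek_links(X: np.ndarray, y: np.ndarray) -> list[tuple[int, int]]:
    """All opposite-class mutual-nearest-neighbour pairs (by row index).

    Nearest-neighbour ties break toward the lowest index.  Returned pairs
    are sorted, each as ``(i, j)`` with ``i < j``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(X)
    if n < 2:
        return []
    d = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    nn = d.argmin(axis=1)  # argmin takes the lowest index on ties
    links = set()
    for i in range(n):
        j = nn[i]
        if nn[j] == i and y[i] != y[j]:
            links.add((min(i, j), max(i, j)))
    return sorted(links)


def remove_tomek(
    matrix: FeatureMatrix, remove_both: bool = True, minority: Optional[str] = None
) -> FeatureMatrix:
    """Drop Tomek-link members found on the input set (single pass).

    With ``remove_both=False`` only the majority-class member of each link
    is removed (one-sided cleaning).
    """
    X = matrix.values.to_numpy(dtype=float)
    y = matrix.labels.to_numpy()
    links = tomek_links(X, y)
    if minority is None:
        minority = _minority_label(matrix.labels)
    drop: set[int] = set()
    for i, j in links:
        if remove_both:
            drop.update((i, j))
        else:
            drop.add(i if y[i] != minority else j)
    keep = [i for i in range(len(X)) if i not in drop]
    return FeatureMatrix(
        matrix.values.iloc[keep], matrix.labels.iloc[keep],
        matrix.scaling_bounds, matrix.imputation_means,
    )


def remove_border(matrix: FeatureMatrix, threshold: int = 2) -> FeatureMatrix:
    """Drop instances that are the nearest neighbour of >= ``threshold``
    opposite-class instances (evaluated once, on the input set)."""
    X = matrix.values.to_numpy(dtype=float)
    y = matrix.labels.to_numpy()
    n = len(X)
    if n < 2:
        return matrix
    d = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    nn = d.argmin(axis=1)
    counts = np.zeros(n, dtype=int)
    for i in range(n):
        j = nn[i]
        if y[i] != y[j]:
            counts[j] += 1
    keep = [i for i in range(n) if counts[i] < threshold]
    return FeatureMatrix(
        matrix.values.iloc[keep], matrix.labels.iloc[keep],
        matrix.scaling_bounds, matrix.imputation_means,
    )


def _default_filter(seed: int) -> MLPClassifier:
    return MLPClassifier(
        hidden_layer_sizes=(8,), max_iter=300, random_state=seed, tol=1e-3
    )


def remove_misclassified(
    matrix: FeatureMatrix,
    filter_factory: Optional[Callable[[int], object]] = None,
    seed: int = 0,
    strict: bool = False,
) -> FeatureMatrix:
    """Fit a filter classifier on the set and drop what it misclassifies.

    The filter model is discarded afterwards.  If fitting fails, a warning
    is emitted and the input is returned unchanged (``strict=True`` turns
    this into an error).
    """
    factory = filter_factory or _default_filter
    X = matrix.values.to_numpy(dtype=float)
    y = matrix.labels.to_numpy()
    model = factory(seed)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X, y)
            pred = model.predict(X)
    except Exception as exc:  # pragma: no cover - defensive
        if strict:
            raise
        warnings.warn(f"misclassification filter failed to fit ({exc}); skipping")
        return matrix
    keep = np.flatnonzero(pred == y)
    return FeatureMatrix(
        matrix.values.iloc[keep], matrix.labels.iloc[keep],
        matrix.scaling_bounds, matrix.imputation_means,
    )


def preprocess(
    train: FeatureMatrix, config: PreprocessConfig = PreprocessConfig()
) -> tuple[FeatureMatrix, dict]:
    """Run the imbalance cascade on an (imputed) training matrix.

    Order: SMOTE -> Tomek-link removal -> border removal ->
    misclassification filtering.  Returns the processed matrix and a
    per-step bookkeeping report.
    """
    report: dict[str, int] = {"n_input": len(train)}
    current = train
    minority = _minority_label(train.labels)

    if config.smote_enabled:
        mask = current.labels == minority
        minority_X = current.values[mask].to_numpy(dtype=float)
        synth = smote(minority_X, config.smote_percent, config.smote_k, config.seed)
        synth_df = pd.DataFrame(
            synth,
            columns=current.values.columns,
            index=[f"__smote_{i:05d}" for i in range(len(synth))],
        )
        values = pd.concat([current.values, synth_df])
        labels = pd.concat(
            [current.labels, pd.Series(minority, index=synth_df.index, name="label")]
        )
        current = FeatureMatrix(values, labels, train.scaling_bounds, train.imputation_means)
        report["n_smote_synthetic"] = len(synth)
    else:
        report["n_smote_synthetic"] = 0

    def guarded(step, name):
        # a cleaning step that would eliminate a whole class is skipped:
        # the classifiers downstream need both classes present
        nonlocal current
        before = len(current)
        cleaned = step(current)
        if cleaned.labels.nunique() < 2:
            report[name] = 0
            report[f"{name.replace('n_', '')}_skipped"] = 1
        else:
            current = cleaned
            report[name] = before - len(current)

    if config.tomek_enabled:
        guarded(
            lambda m: remove_tomek(m, config.tomek_remove_both, minority),
            "n_tomek_removed",
        )
    else:
        report["n_tomek_removed"] = 0

    if config.border_enabled:
        guarded(lambda m: remove_border(m, config.border_threshold), "n_border_removed")
    else:
        report["n_border_removed"] = 0

    if config.misclassified_enabled:
        guarded(
            lambda m: remove_misclassified(m, seed=config.seed, strict=config.strict_filter),
            "n_misclassified_removed",
        )
    else:
        report["n_misclassified_removed"] = 0

    report["n_output"] = len(current)
    return current, report
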
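"""Per-drug feature vectors from per-target network centralities.

A drug's feature vector is the arithmetic mean, over its targets, of each
centrality measure.  Similarity-network (PSIN) measures are first moved to
the log10 scale — ``log10(x + 1)`` for the count-like degree and
betweenness (so zeros map to zero), ``log10(x)`` for the strictly positive
closeness and constraint.  Interaction-network (PPI) measures are averaged
on the raw scale by default.  Targets lacking a value for some measure
simply drop out of that mean; a feature with no contributing target is
missing and is later mean-imputed, separately within the training and the
test matrix.  Finally every feature is min-max scaled to [0, 1] with bounds
fitted on the training matrix only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .drugs import DrugRecord

__all__ = [
    "FEATURE_NAMES",
    "FeatureMatrix",
    "aggregate_drug",
    "build_feature_matrix",
    "impute_missing",
    "scale_unit",
]

FEATURE_NAMES = [
    "psin_degree",
    "psin_betweenness",
    "psin_closeness",
    "psin_constraint",
    "ppi_degree",
    "ppi_betweenness",
    "ppi_closeness",
    "ppi_constraint",
]

_MEASURES = ["degree", "betweenness", "closeness", "burts_constraint"]
_SHORT = {"degree": "degree", "betweenness": "betweenness",
          "closeness": "closeness", "burts_constraint": "constraint"}


class AggregationError(ValueError):
    pass


class ImputationError(ValueError):
    pass


@dataclass
class FeatureMatrix:
    """Per-drug features with labels and (optional) fitted scaling bounds."""

    values: pd.DataFrame  # index: drug_id; columns: feature names
    labels: pd.Series  # aligned with values.index
    scaling_bounds: Optional[pd.DataFrame] = None  # rows: min, max
    imputation_means: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        self.labels = self.labels.reindex(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(
            self.values.copy(),
            self.labels.copy(),
            None if self.scaling_bounds is None else self.scaling_bounds.copy(),
            None if self.imputation_means is None else self.imputation_means.copy(),
        )

    def __len__(self) -> int:
        return len(self.values)


def _transform_psin(measure: str, vals: np.ndarray) -> np.ndarray:
    if measure in ("degree", "betweenness"):
        return np.log10(vals + 1.0)
    return np.log10(vals)


def _aggregate_one(
    targets: Iterable[str], table: Optional[pd.DataFrame], measure: str, log10: bool
) -> float:
    if table is None:
        return np.nan
    present = [t for t in targets if t in table.index]
    if not present:
        return np.nan
    vals = table.loc[present, measure].to_numpy(dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return np.nan
    if log10:
        vals = _transform_psin(measure, vals)
    return float(vals.mean())


def aggregate_drug(
    drug: DrugRecord,
    psin_table: Optional[pd.DataFrame] = None,
    ppi_table: Optional[pd.DataFrame] = None,
    log10_psin: bool = True,
    log10_ppi: bool = False,
    feature_names: Sequence[str] = tuple(FEATURE_NAMES),
) -> dict[str, float]:
    """Aggregate the per-target centralities of one drug into features.

    Raises :class:`AggregationError` when no target of the drug appears in
    any supplied centrality table.
    """
    if not any(
        t in tab.index
        for tab in (psin_table, ppi_table) if tab is not None
        for t in drug.targets
    ):
        raise AggregationError(
            f"drug {drug.drug_id!r}: no target present in any centrality table"
        )
    out: dict[str, float] = {}
    for measure in _MEASURES:
        short = _SHORT[measure]
        name = f"psin_{short}"
        if name in feature_names:
            out[name] = _aggregate_one(drug.targets, psin_table, measure, log10_psin)
        name = f"ppi_{short}"
        if name in feature_names:
            out[name] = _aggregate_one(drug.targets, ppi_table, measure, log10_ppi)
    return out


def build_feature_matrix(
    drugs: Sequence[DrugRecord],
    psin_table: Optional[pd.DataFrame] = None,
    ppi_table: Optional[pd.DataFrame] = None,
    log10_psin: bool = True,
    log10_ppi: bool = False,
    feature_names: Optional[Sequence[str]] = None,
) -> FeatureMatrix:
    """Feature matrix over a list of drugs (raw, unimputed, unscaled)."""
    if feature_names is None:
        feature_names = []
        if psin_table is not None:
            feature_names += [f for f in FEATURE_NAMES if f.startswith("psin_")]
        if ppi_table is not None:
            feature_names += [f for f in FEATURE_NAMES if f.startswith("ppi_")]
    rows = {}
    labels = {}
    for drug in drugs:
        rows[drug.drug_id] = aggregate_drug(
            drug, psin_table, ppi_table, log10_psin, log10_ppi, feature_names
        )
        labels[drug.drug_id] = drug.label
    values = pd.DataFrame.from_dict(rows, orient="index", columns=list(feature_names))
    values.index.name = "drug_id"
    return FeatureMatrix(values=values, labels=pd.Series(labels, name="label"))


def impute_missing(matrix: FeatureMatrix) -> FeatureMatrix:
    """Replace each missing entry by the within-matrix mean of its feature.

    Called independently on training and test matrices so no statistic
    crosses the split.  A feature missing everywhere is an error.
    """
    values = matrix.values.copy()
    all_missing = values.columns[values.isna().all(axis=0)]
    if len(all_missing):
        raise ImputationError(
            f"feature(s) missing for every drug: {list(all_missing)}"
        )
    means = values.mean(axis=0)
    values = values.fillna(means)
    return FeatureMatrix(values, matrix.labels.copy(), matrix.scaling_bounds, means)


def scale_unit(
    train: FeatureMatrix, others: Sequence[FeatureMatrix] = ()
) -> tuple[FeatureMatrix, list[FeatureMatrix]]:
    """Min-max scale to [0, 1] with bounds fitted on the training matrix.

    Other matrices are transformed with the training bounds and clipped to
    [0, 1].  A constant training feature maps to 0.5 everywhere.
    """
    lo = train.values.min(axis=0)
    hi = train.values.max(axis=0)
    span = hi - lo
    bounds = pd.DataFrame({"min": lo, "max": hi}).T

    def apply(m: FeatureMatrix) -> FeatureMatrix:
        vals = m.values.copy()
        for col in vals.columns:
            if span[col] == 0:
                vals[col] = 0.5
            else:
                vals[col] = ((vals[col] - lo[col]) / span[col]).clip(0.0, 1.0)
        return FeatureMatrix(vals, m.labels.copy(), bounds.copy(), m.imputation_means)

    return apply(train), [apply(m) for m in others]
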
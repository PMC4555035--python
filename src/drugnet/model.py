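"""Model/Results facade over the drug-safety pipeline.

:class:`DrugSafetyModel` bundles a labelled drug-target dataset with the
per-protein network centralities and the ensemble configuration;
``fit()`` runs the repeated hold-out evaluation and trains the final
ensemble, returning a :class:`DrugSafetyResults` with AUC estimates and
their uncertainty, per-drug Rejection Scores, and a ``summary()`` table.
Candidate scoring and plotting hang off the results object.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import classify
from .centrality import centrality_table
from .classify import (
    ClassifierSpec,
    EvaluationReport,
    RejectionScore,
    default_specs,
    predict_problematic_prob,
    rejection_score,
    repeated_holdout,
    rs_summary,
    train,
)
from .drugs import DrugRecord
from .features import FeatureMatrix, build_feature_matrix, impute_missing, scale_unit
from .imbalance import PreprocessConfig, preprocess
from .network import ProteinNetwork

__all__ = ["DrugSafetyModel", "DrugSafetyResults"]


class DrugSafetyModel:
    """Ensemble rejection-scoring model over drug-target network features.

    Parameters
    ----------
    drugs
        Labelled drug records (approved / problematic), already filtered.
    psin_table, ppi_table
        Per-protein centrality tables (see :func:`~drugnet.centrality.centrality_table`).
    specs
        Classifier specs; defaults to the three heterogeneous families.
    preprocess_config
        Imbalance-correction configuration for the training split.
    """

    def __init__(
        self,
        drugs: Sequence[DrugRecord],
        psin_table: Optional[pd.DataFrame] = None,
        ppi_table: Optional[pd.DataFrame] = None,
        specs: Optional[Sequence[ClassifierSpec]] = None,
        preprocess_config: Optional[PreprocessConfig] = None,
    ):
        if psin_table is None and ppi_table is None:
            raise ValueError("at least one centrality table is required")
        self.drugs = list(drugs)
        self.psin_table = psin_table
        self.ppi_table = ppi_table
        self.specs = list(specs) if specs is not None else None
        self.preprocess_config = preprocess_config
        self.raw = build_feature_matrix(self.drugs, psin_table, ppi_table)

    @classmethod
    def from_networks(
        cls,
        drugs: Sequence[DrugRecord],
        psin: Optional[ProteinNetwork] = None,
        ppi: Optional[ProteinNetwork] = None,
        **kwargs,
    ) -> "DrugSafetyModel":
        """Build the model directly from networks, computing centralities."""
        psin_table = centrality_table(psin) if psin is not None else None
        ppi_table = centrality_table(ppi) if ppi is not None else None
        return cls(drugs, psin_table, ppi_table, **kwargs)

    def fit(
        self, n_repeats: int = 20, train_fraction: float = 0.7, seed: int = 0
    ) -> "DrugSafetyResults":
        """Evaluate by repeated hold-out, then train the final ensemble.

        The final ensemble is trained on the full (imputed, scaled,
        rebalanced) dataset and used for in-sample Rejection Scores and
        candidate scoring.
        """
        specs = self.specs if self.specs is not None else default_specs(seed)
        config = self.preprocess_config or PreprocessConfig(seed=seed)
        report = repeated_holdout(
            self.drugs, self.raw, specs, n_repeats, train_fraction, config, seed
        )
        full = impute_missing(
            FeatureMatrix(self.raw.values.copy(), self.raw.labels.copy())
        )
        full_scaled, _ = scale_unit(full)
        full_train, _ = preprocess(full_scaled, config)
        models = [train(s, full_train) for s in specs]
        probs = np.column_stack(
            [predict_problematic_prob(m, full_scaled) for m in models]
        )
        scores = [
            rejection_score(list(probs[i]), drug_id=d)
            for i, d in enumerate(full_scaled.values.index)
        ]
        return DrugSafetyResults(
            model=self,
            specs=specs,
            config=config,
            report=report,
            final_models=models,
            full_scaled=full_scaled,
            rejection_scores=scores,
            seed=seed,
        )


class DrugSafetyResults:
    """Fit results: AUC estimates, Rejection Scores, summary and plots."""

    def __init__(self, model, specs, config, report: EvaluationReport,
                 final_models, full_scaled, rejection_scores, seed):
        self.model = model
        self.specs = specs
        self.config = config
        self.report = report
        self.final_models = final_models
        self.full_scaled = full_scaled
        self.rejection_scores: list[RejectionScore] = rejection_scores
        self.seed = seed

    # -- estimates -----------------------------------------------------

    @property
    def auc_values(self) -> list[float]:
        return self.report.auc_values

    @property
    def mean_auc(self) -> float:
        return self.report.mean_auc

    @property
    def auc_se(self) -> float:
        v = np.asarray(self.report.auc_values)
        return float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else float("nan")

    @property
    def scores_frame(self) -> pd.DataFrame:
        rows = {
            s.drug_id: (s.score, *s.component_probs) for s in self.rejection_scores
        }
        df = pd.DataFrame.from_dict(
            rows, orient="index", columns=["rs", "p1", "p2", "p3"]
        )
        df.index.name = "drug_id"
        df["label"] = self.full_scaled.labels
        return df

    def rs_table(self, cutoffs=(0.0, 0.02, 0.1, 0.25, 0.5, 0.75, 0.9, 0.95)) -> pd.DataFrame:
        labels = self.full_scaled.labels.to_dict()
        return rs_summary(self.rejection_scores, labels, cutoffs)

    # -- scoring new candidates ---------------------------------------

    def score(self, candidates: Sequence[DrugRecord]) -> list[RejectionScore]:
        """Leave-matching-targets-out Rejection Scores for new drugs."""
        raw_cand = build_feature_matrix(
            candidates, self.model.psin_table, self.model.ppi_table
        )
        return classify.score_candidates(
            self.model.drugs, candidates, self.model.raw, raw_cand,
            self.specs, self.config, self.seed,
        )

    # -- presentation --------------------------------------------------

    def summary(self) -> str:
        counts = pd.Series([d.label for d in self.model.drugs]).value_counts()
        lines = [
            "Drug Safety Ensemble Results",
            "=" * 60,
            f"Drugs:             {len(self.model.drugs)} "
            f"({', '.join(f'{k}: {v}' for k, v in counts.items())})",
            f"Features:          {', '.join(self.model.raw.feature_names)}",
            f"Hold-out repeats:  {self.report.n_repeats} "
            f"(train fraction 0.7, stratified, target-set hygiene)",
            "-" * 60,
            "AUC (problematic vs approved, positive = problematic)",
        ]
        for fam, vals in self.report.per_spec_auc.items():
            v = np.asarray(vals)
            lines.append(f"  {fam:<20s} {v.mean():.3f} (sd {v.std(ddof=1):.3f})")
        lines.append(
            f"  {'ensemble (RS)':<20s} {self.mean_auc:.3f} (se {self.auc_se:.3f})"
        )
        lines.append("-" * 60)
        lines.append("Rejection Score by class (in-sample, final ensemble):")
        df = self.scores_frame
        for label, grp in df.groupby("label"):
            q = grp["rs"].quantile([0.25, 0.5, 0.75])
            lines.append(
                f"  {label:<12s} median {q[0.5]:.3f}  IQR [{q[0.25]:.3f}, {q[0.75]:.3f}]"
            )
        return "\n".join(lines)

    def plot_scores(self, ax=None):
        """Histogram of Rejection Scores per class."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.scores_frame
        for label, grp in df.groupby("label"):
            ax.hist(grp["rs"], bins=20, alpha=0.6, label=str(label))
        ax.set_xlabel("Rejection Score")
        ax.set_ylabel("drugs")
        ax.legend()
        return ax

    def plot_auc(self, ax=None):
        """Distribution of per-repeat ensemble AUC values."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.auc_values, bins=15)
        ax.axvline(self.mean_auc, color="k", linestyle="--")
        ax.set_xlabel("hold-out AUC")
        ax.set_ylabel("repeats")
        return ax
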
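"""drugnet: protein similarity networks and ensemble drug-safety scoring.

Builds protein similarity networks (PSIN) from bidirectional sequence
similarity hits, computes the network centralities that separate targets
of approved from problematic drugs (degree, betweenness, closeness,
Burt's constraint), aggregates them into per-drug features, corrects the
class imbalance, and trains a heterogeneous classifier ensemble whose
mean problematic-probability is a drug's Rejection Score.
"""

from .network import (
    BlastParams,
    NetworkSummary,
    ProteinNetwork,
    SimilarityHit,
    build_psin,
    load_edge_list,
    network_summary,
    parse_blast_tabular,
)
from .centrality import (
    DangerZoneFlags,
    DangerZoneThresholds,
    centrality_table,
    danger_zone,
)
from .drugs import (
    DrugRecord,
    LabeledDataset,
    assign_label,
    dedupe_conflicting,
    filter_affinity,
    load_drug_targets,
    remove_failure_group,
    restrict_to_networks,
    split_train_test,
)
from .features import FeatureMatrix, aggregate_drug, build_feature_matrix
from .imbalance import PreprocessConfig, preprocess, smote, tomek_links
from .classify import (
    ClassifierSpec,
    RejectionScore,
    RotationForestClassifier,
    auc,
    default_specs,
    rejection_score,
    repeated_holdout,
    rs_summary,
    score_candidates,
)
from .nulls import (
    neighbor_targeting_test,
    paired_null_eval,
    shuffle_labels_and_targets,
    shuffle_network_labels,
)
from .synthetic import SimulationConfig, generate_blast_fixture, generate_drugs, generate_network
from .model import DrugSafetyModel, DrugSafetyResults

__version__ = "0.1.0"
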
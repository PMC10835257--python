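"""cascadenode: two-step radiomic multiclassification of head-and-neck
primary tumor site from lymph-node feature tables.

The package implements two evaluation pipelines over per-patient radiomic
feature tables: a direct four-class classifier (P1) and a two-step cascade
(P2) that first merges the two minority classes into a transitory 'Fusion'
class and then reclassifies the samples routed to it.  Around the
classifiers it provides ICC-based feature-stability filtering, Spearman
redundancy pruning, five feature selectors with frequency aggregation over
30 seeded partitions, SMOTE/undersampling class rebalancing, and a
class-wise weighted-Shapley explainability statistic.
"""

__version__ = "0.1.0"

from .catalog import FeatureCatalog, build_feature_catalog
from .cohort import (
    CLASSES,
    ClinicalSpec,
    CohortSpec,
    FeatureTable,
    generate_cohort,
    generate_replicate,
)
from .explain import (
    ShapleyReport,
    explain_best_partition,
    select_best_partition,
    shapley_values,
    weighted_shapley,
)
from .models import (
    EvalResult,
    ModelSpec,
    aggregate,
    balanced_accuracy,
    general_accuracy,
    train_model,
)
from .partitioning import (
    BalanceSpec,
    PartitionPlan,
    balance_training_set,
    make_partitions,
    smote_oversample,
)
from .pipelines import (
    CandidateScore,
    PipelineConfig,
    config_grid,
    elect_feature_set,
    merge_minority,
    run_p1,
    run_p2,
)
from .preprocessing import (
    correlation_prune,
    icc,
    stability_filter,
    zscore_apply,
    zscore_fit,
)
from .selection import (
    SelectionFrequency,
    aggregate_frequency,
    mrmr_select,
    nca_select,
    sbs,
    sffs,
    sfs,
)

__all__ = [
    "__version__",
    "FeatureCatalog", "build_feature_catalog",
    "CLASSES", "ClinicalSpec", "CohortSpec", "FeatureTable",
    "generate_cohort", "generate_replicate",
    "ShapleyReport", "explain_best_partition", "select_best_partition",
    "shapley_values", "weighted_shapley",
    "EvalResult", "ModelSpec", "aggregate", "balanced_accuracy",
    "general_accuracy", "train_model",
    "BalanceSpec", "PartitionPlan", "balance_training_set",
    "make_partitions", "smote_oversample",
    "CandidateScore", "PipelineConfig", "config_grid", "elect_feature_set",
    "merge_minority", "run_p1", "run_p2",
    "correlation_prune", "icc", "stability_filter", "zscore_apply", "zscore_fit",
    "SelectionFrequency", "aggregate_frequency", "mrmr_select", "nca_select",
    "sbs", "sffs", "sfs",
]
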
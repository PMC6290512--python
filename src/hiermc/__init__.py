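"""hiermc: hierarchical meta-classification for imbalanced clinical cohorts.

Stratifies visit records of a chronic-disease cohort into severity stages
(3/4/5) under severe class imbalance by (1) partitioning the majority
class into balanced subsets, (2) stacking an ensemble of base classifiers
through a categorical naïve-Bayes meta-classifier for the coarse
majority-vs-combined-minority decision, and (3) refining the combined
minority class into its constituent stages. Ships a synthetic EHR-like
cohort generator, comparator strategies (baseline, random under-sampling,
SMOTE, simple meta-classification) and a temporal evaluation harness.
"""

from .balancing import BalancedSubsets, build_balanced_sets, compute_num_partitions
from .data_model import (
    COMBINED_45,
    STAGES,
    FeatureSchema,
    RecordSet,
    TemporalSplit,
    VisitRecord,
    apply_feature_exclusions,
    class_counts,
    complete_case_filter,
    read_records,
    read_schema,
    temporal_split,
    write_records,
    write_schema,
)
from .evaluation import (
    ClassMetrics,
    ExperimentResult,
    class_metrics,
    compute_metrics,
    confusion_counts,
    evaluate_labels,
    macro_average,
    run_comparison,
    run_truncation_experiment,
)
from .meta import (
    BaseClassifierSpec,
    CoarseModel,
    MetaRepresentation,
    NaiveBayesMeta,
    build_meta_representation,
    coarse_predict,
    fit_coarse,
    fit_naive_bayes_meta,
    fit_simple_meta_classifier,
    train_base_classifiers,
)
from .pipeline import (
    STRATEGIES,
    HierMCModel,
    fit_comparator,
    fit_hier_mc,
    predict_hier_mc,
)
from .refinement import RefinementModel, fit_refinement, refine_predict
from .synthetic import GeneratorConfig, default_schema, generate_cohort, study_replica

__version__ = "0.1.0"

__all__ = [
    "BalancedSubsets",
    "BaseClassifierSpec",
    "COMBINED_45",
    "ClassMetrics",
    "CoarseModel",
    "ExperimentResult",
    "FeatureSchema",
    "GeneratorConfig",
    "HierMCModel",
    "MetaRepresentation",
    "NaiveBayesMeta",
    "RecordSet",
    "RefinementModel",
    "STAGES",
    "STRATEGIES",
    "TemporalSplit",
    "VisitRecord",
    "apply_feature_exclusions",
    "build_balanced_sets",
    "build_meta_representation",
    "class_counts",
    "class_metrics",
    "coarse_predict",
    "complete_case_filter",
    "compute_metrics",
    "compute_num_partitions",
    "confusion_counts",
    "default_schema",
    "evaluate_labels",
    "fit_coarse",
    "fit_comparator",
    "fit_hier_mc",
    "fit_naive_bayes_meta",
    "fit_refinement",
    "fit_simple_meta_classifier",
    "generate_cohort",
    "macro_average",
    "predict_hier_mc",
    "read_records",
    "read_schema",
    "refine_predict",
    "run_comparison",
    "run_truncation_experiment",
    "study_replica",
    "temporal_split",
    "train_base_classifiers",
    "write_records",
    "write_schema",
]
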
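"""Refinement classification: stage 4 versus stage 5.

Records the coarse step assigns to the combined minority class are split
into their constituent stages by a single two-class classifier trained on
the true stage-4/5 training records under the original feature
representation. The residual 4:5 imbalance (~2:1) is mild and is left
untouched by default; an optional flag reuses the balanced-subset
meta-classification machinery between the two stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .balancing import build_balanced_sets, compute_num_partitions
from .data_model import RecordSet
from .meta import (
    BaseClassifierSpec,
    CoarseModel,
    coarse_predict,
    fit_coarse,
    make_estimator,
)


@dataclass
class RefinementModel:
    """Fitted two-class (4 vs 5) model over the original features."""

    classifier: object  # fitted estimator, or a CoarseModel in balanced mode
    spec: BaseClassifierSpec
    n_training_records: int
    balanced: bool = False

    @property
    def classes(self) -> tuple[int, int]:
        return (4, 5)


def fit_refinement(
    train: RecordSet,
    spec: BaseClassifierSpec,
    balance: bool = False,
) -> RefinementModel:
    """Fit the refinement classifier on the true stage-4/5 training subset.

    Training uses the records' original feature vectors — never the coarse
    step's predictions — and, by default, no re-balancing between the two
    stages. ``balance=True`` instead partitions the larger of the two
    stages into balanced blocks and fits the same ensemble-plus-naïve-Bayes
    machinery used by the coarse step.
    """
    idx = np.flatnonzero((train.stages == 4) | (train.stages == 5))
    sub = train.subset(idx)
    counts = sub.class_counts()
    if counts[4] == 0 or counts[5] == 0:
        raise ValueError(
            f"refinement training requires both stages 4 and 5; got {counts}"
        )
    if not balance:
        est = make_estimator(spec, seed=spec.seed)
        est.fit(sub.features, sub.stages)
        return RefinementModel(est, spec, n_training_records=len(sub))

    majority = 4 if counts[4] >= counts[5] else 5
    m = compute_num_partitions(counts[majority], counts[9 - majority])
    subsets = build_balanced_sets(sub, majority_label=majority, M=m, seed=spec.seed)
    coarse = fit_coarse(
        sub,
        subsets,
        spec,
        target_map={4: 4, 5: 5},
        tie_priority=(5, 4),
    )
    return RefinementModel(coarse, spec, n_training_records=len(sub), balanced=True)


def refine_predict(model: RefinementModel, rs: RecordSet) -> np.ndarray:
    """Assign stage 4 or 5 to every input record; no record may remain in
    the combined class."""
    if len(rs) == 0:
        return np.empty(0, dtype=np.int64)
    if model.balanced:
        return coarse_predict(model.classifier, rs)
    if rs.features.shape[1] != model.classifier.n_features_in_:
        raise ValueError(
            f"record dimension {rs.features.shape[1]} does not match the "
            f"refinement model's training dimension {model.classifier.n_features_in_}"
        )
    return model.classifier.predict(rs.features).astype(np.int64)
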
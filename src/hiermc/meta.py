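"""Coarse classification via ensemble meta-classification (stacking).

M base-classifiers are trained, one per balanced subset, to separate the
majority stage from the combined minority class. Each record is then
re-represented as the M-dimensional vector of hard labels the base
classifiers assign to it, and a categorical naïve-Bayes meta-classifier —
implemented here from scratch with Laplace smoothing and log-space
arithmetic — makes the final coarse decision. Ties break toward the
combined minority class: missing an advanced-stage case is the costly
error in risk stratification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.tree import DecisionTreeClassifier

from .balancing import BalancedSubsets
from .data_model import COMBINED_45, RecordSet

logger = logging.getLogger(__name__)

#: Label map collapsing the two advanced stages into the combined class.
COARSE_TARGET_MAP: dict[int, int] = {3: 3, 4: COMBINED_45, 5: COMBINED_45}

#: Identity map used when base classifiers keep the three original stages.
IDENTITY_TARGET_MAP: dict[int, int] = {3: 3, 4: 4, 5: 5}

_METHODS = ("random_forest", "logistic_regression", "naive_bayes", "decision_tree")


@dataclass(frozen=True)
class BaseClassifierSpec:
    """Family, hyperparameters and seed of the simple base classifiers.

    The default family is a 100-tree random forest with unlimited depth;
    model j of an ensemble is seeded with ``seed + j``.
    """

    method: str = "random_forest"
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}, got {self.method!r}")


def make_estimator(spec: BaseClassifierSpec, seed: int) -> BaseEstimator:
    """Instantiate one (unfitted) scikit-learn estimator for the spec."""
    hp = dict(spec.hyperparameters)
    if spec.method == "random_forest":
        hp.setdefault("n_estimators", 100)
        return RandomForestClassifier(random_state=seed, **hp)
    if spec.method == "logistic_regression":
        hp.setdefault("max_iter", 1000)
        return LogisticRegression(random_state=seed, **hp)
    if spec.method == "naive_bayes":
        return GaussianNB(**hp)
    return DecisionTreeClassifier(random_state=seed, **hp)


@dataclass
class MetaRepresentation:
    """Per-record M-dimensional vectors of base-classifier labels."""

    vectors: np.ndarray  # (n, M) integer labels
    label_alphabet: tuple[int, ...]

    def __post_init__(self) -> None:
        bad = set(np.unique(self.vectors)) - set(self.label_alphabet) if self.vectors.size else set()
        if bad:
            raise ValueError(f"labels outside alphabet: {sorted(bad)}")


@dataclass
class NaiveBayesMeta:
    """Categorical naïve Bayes over the M label features.

    ``log_cond[j, c, v]`` is log P(label of base-classifier j = alphabet[v]
    | class = classes[c]), Laplace-smoothed with ``alpha``; priors are the
    raw class frequencies. Prediction maximises the log posterior; exact
    ties resolve to the earliest class in ``tie_priority``.
    """

    classes: np.ndarray
    alphabet: np.ndarray
    log_priors: np.ndarray
    log_cond: np.ndarray
    alpha: float
    tie_priority: np.ndarray

    def posterior_scores(self, vectors: np.ndarray) -> np.ndarray:
        """(n, n_classes) unnormalised log posterior scores."""
        vidx = np.searchsorted(self.alphabet, vectors)
        if (vidx >= len(self.alphabet)).any() or (
            self.alphabet[np.clip(vidx, 0, len(self.alphabet) - 1)] != vectors
        ).any():
            raise ValueError("meta vectors contain labels unseen in training alphabet")
        n, m = vectors.shape
        scores = np.tile(self.log_priors, (n, 1))
        for j in range(m):
            scores += self.log_cond[j, :, vidx[:, j]]
        return scores

    def predict(self, vectors: np.ndarray) -> np.ndarray:
        if vectors.shape[0] == 0:
            return np.empty(0, dtype=np.int64)
        scores = self.posterior_scores(vectors)
        order = np.array(
            [int(np.flatnonzero(self.classes == c)[0]) for c in self.tie_priority]
        )
        # argmax over priority-ordered columns: first maximum wins the tie
        pick = np.argmax(scores[:, order], axis=1)
        return self.tie_priority[pick]


def fit_naive_bayes_meta(
    meta: MetaRepresentation,
    labels: np.ndarray,
    alpha: float = 1.0,
    tie_priority: Sequence[int] | None = None,
) -> NaiveBayesMeta:
    """Fit the categorical naïve-Bayes meta-classifier.

    priors[c] = N_c / N; conditionals[j][c][v] =
    (count(label_j = v, class = c) + alpha) / (N_c + alpha·|alphabet|).
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("meta training labels contain a single class")
    alphabet = np.asarray(sorted(meta.label_alphabet))
    n, m = meta.vectors.shape
    if n != len(labels):
        raise ValueError("labels must align with meta vectors")

    vidx = np.searchsorted(alphabet, meta.vectors)
    log_priors = np.empty(len(classes))
    log_cond = np.empty((m, len(classes), len(alphabet)))
    for c_i, c in enumerate(classes):
        rows = labels == c
        n_c = int(rows.sum())
        log_priors[c_i] = np.log(n_c / n)
        for j in range(m):
            counts = np.bincount(vidx[rows, j], minlength=len(alphabet))
            log_cond[j, c_i] = np.log(
                (counts + alpha) / (n_c + alpha * len(alphabet))
            )
    if tie_priority is None:
        # prefer the more severe label: combined class first, then 5 > 4 > 3
        tie_priority = sorted(classes, key=lambda c: (c != COMBINED_45, -c))
    tp = np.asarray(list(tie_priority))
    if sorted(tp.tolist()) != sorted(classes.tolist()):
        raise ValueError("tie_priority must be a permutation of the classes")
    return NaiveBayesMeta(
        classes=classes,
        alphabet=alphabet,
        log_priors=log_priors,
        log_cond=log_cond,
        alpha=alpha,
        tie_priority=tp,
    )


def train_base_classifiers(
    subsets: BalancedSubsets,
    spec: BaseClassifierSpec,
    target_map: Mapping[int, int] = COARSE_TARGET_MAP,
) -> list[BaseEstimator]:
    """Fit one base classifier per balanced subset; model j is trained only
    on subset j with stages mapped through ``target_map`` and seeded
    ``spec.seed + j``."""
    if not subsets.subsets:
        raise ValueError("no balanced subsets supplied")
    models = []
    for j, sub in enumerate(subsets.subsets):
        y = _map_labels(sub.stages, target_map)
        if len(np.unique(y)) < 2:
            raise ValueError(f"balanced subset {j} contains a single class")
        est = make_estimator(spec, seed=spec.seed + j)
        est.fit(sub.features, y)
        models.append(est)
    return models


def _map_labels(stages: np.ndarray, target_map: Mapping[int, int]) -> np.ndarray:
    return np.vectorize(target_map.__getitem__, otypes=[np.int64])(stages)


def build_meta_representation(
    models: Sequence[BaseEstimator], rs: RecordSet
) -> MetaRepresentation:
    """Re-represent each record as the vector of the M base labels, in
    model order."""
    if rs.features.shape[1] != models[0].n_features_in_:
        raise ValueError(
            f"record dimension {rs.features.shape[1]} does not match the "
            f"base classifiers' training dimension {models[0].n_features_in_}"
        )
    if len(rs) == 0:
        alphabet = tuple(int(c) for c in models[0].classes_)
        return MetaRepresentation(
            np.empty((0, len(models)), dtype=np.int64), alphabet
        )
    cols = [m.predict(rs.features).astype(np.int64) for m in models]
    vectors = np.column_stack(cols)
    alphabet = tuple(sorted({int(c) for m in models for c in m.classes_}))
    return MetaRepresentation(vectors, alphabet)


@dataclass
class CoarseModel:
    """Fitted coarse classifier: M base models plus the naïve-Bayes meta."""

    base_models: list[BaseEstimator]
    nb: NaiveBayesMeta
    spec: BaseClassifierSpec
    M: int
    target_map: dict[int, int]
    n_features: int


def fit_coarse(
    train: RecordSet,
    subsets: BalancedSubsets,
    spec: BaseClassifierSpec,
    alpha: float = 1.0,
    target_map: Mapping[int, int] = COARSE_TARGET_MAP,
    meta_training: str = "insample",
    tie_priority: Sequence[int] | None = None,
) -> CoarseModel:
    """Train base classifiers on the balanced subsets and the naïve-Bayes
    meta-classifier on the label vectors of the *full* training set.

    ``meta_training="out_of_fold"`` replaces, for each majority record in
    block j, the in-sample entry j with the prediction of model (j+1) mod M
    (which did not train on that record); minority records appear in every
    balanced subset, so their entries are unavoidably in-sample.
    """
    if meta_training not in ("insample", "out_of_fold"):
        raise ValueError(f"unknown meta_training mode {meta_training!r}")
    models = train_base_classifiers(subsets, spec, target_map)
    meta = build_meta_representation(models, train)
    if meta_training == "out_of_fold" and subsets.M > 1:
        vectors = meta.vectors.copy()
        for j, block in enumerate(subsets.majority_blocks):
            alt = models[(j + 1) % subsets.M]
            vectors[block, j] = alt.predict(train.features[block]).astype(np.int64)
        meta = MetaRepresentation(vectors, meta.label_alphabet)
    coarse_labels = _map_labels(train.stages, target_map)
    nb = fit_naive_bayes_meta(meta, coarse_labels, alpha=alpha, tie_priority=tie_priority)
    logger.info(
        "coarse model: M=%d, subset size=%d, alphabet=%s",
        subsets.M,
        2 * subsets.minority_size,
        meta.label_alphabet,
    )
    return CoarseModel(
        base_models=models,
        nb=nb,
        spec=spec,
        M=subsets.M,
        target_map=dict(target_map),
        n_features=train.features.shape[1],
    )


def coarse_predict(model: CoarseModel, rs: RecordSet) -> np.ndarray:
    """Coarse labels for each record: build its base-label vector, then
    take the naïve-Bayes posterior argmax (ties to the combined class)."""
    meta = build_meta_representation(model.base_models, rs)
    return model.nb.predict(meta.vectors)


def fit_simple_meta_classifier(
    train: RecordSet,
    spec: BaseClassifierSpec,
    M: int | None = None,
    seed: int | None = None,
    alpha: float = 1.0,
    subset_mode: str = "partition",
) -> CoarseModel:
    """Non-hierarchical meta-classifier comparator.

    Uses the same balanced-subset machinery as the coarse step (majority
    stage 3 versus the pooled rest) but the base classifiers keep the three
    original stage labels, and the naïve-Bayes meta predicts directly among
    {3, 4, 5} (ties to the more severe stage). Serves as the "simple MC"
    strategy in comparisons.
    """
    from .balancing import build_balanced_sets, compute_num_partitions

    counts = train.class_counts()
    if min(counts.values()) == 0:
        raise ValueError(f"all three stages required, got {counts}")
    seed = spec.seed if seed is None else seed
    spec = BaseClassifierSpec(spec.method, dict(spec.hyperparameters), seed)
    minority = counts[4] + counts[5]
    if M is None:
        M = compute_num_partitions(counts[3], minority)
    subsets = build_balanced_sets(train, majority_label=3, M=M, seed=seed, mode=subset_mode)
    return fit_coarse(train, subsets, spec, alpha=alpha, target_map=IDENTITY_TARGET_MAP)
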
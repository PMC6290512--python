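"""Composition of the hierarchical meta-classifier and comparator strategies.

``fit_hier_mc`` chains the pieces: derive M from the coarse class counts,
partition the majority class into balanced subsets, train the base
ensemble and the naïve-Bayes meta (coarse step), and fit the stage-4/5
refinement forest. ``fit_comparator`` provides the alternative strategies
used in head-to-head comparisons — a plain multiclass baseline, random
under-sampling, SMOTE over-sampling, and the non-hierarchical simple
meta-classifier — all behind one fit/predict contract so the evaluation
harness treats every strategy uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from sklearn.multiclass import OneVsRestClassifier
from sklearn.neighbors import NearestNeighbors

from .balancing import build_balanced_sets, compute_num_partitions
from .data_model import COMBINED_45, STAGES, RecordSet
from .meta import (
    BaseClassifierSpec,
    CoarseModel,
    coarse_predict,
    fit_coarse,
    fit_simple_meta_classifier,
    make_estimator,
)
from .refinement import RefinementModel, fit_refinement, refine_predict

STRATEGIES = ("baseline_oaa", "under_sampling", "smote", "simple_mc", "hier_mc")


@dataclass
class HierMCModel:
    """Fitted hierarchical meta-classifier (coarse + refinement)."""

    coarse: CoarseModel
    refine: RefinementModel
    schema_fingerprint: str
    seeds: dict[str, int]
    M: int

    def predict(self, rs: RecordSet) -> np.ndarray:
        return predict_hier_mc(self, rs)


def fit_hier_mc(
    train: RecordSet,
    spec: BaseClassifierSpec | None = None,
    M: int | str = "auto",
    seed: int | None = None,
    alpha: float = 1.0,
    subset_mode: str = "partition",
    meta_training: str = "insample",
    balance_refinement: bool = False,
) -> HierMCModel:
    """Fit the full hierarchical meta-classifier.

    With ``M="auto"`` the partition count is the floor of the
    majority:minority ratio of the coarse task. All randomness (subset
    partitioning, base-model seeds, refinement seed) derives from ``seed``
    (default: ``spec.seed``), so refitting with the same inputs reproduces
    identical predictions.
    """
    spec = spec or BaseClassifierSpec()
    seed = spec.seed if seed is None else seed
    spec = BaseClassifierSpec(spec.method, dict(spec.hyperparameters), seed)
    counts = train.class_counts()
    if min(counts.values()) == 0:
        raise ValueError(f"all three stages required for training, got {counts}")
    minority = counts[4] + counts[5]
    m = compute_num_partitions(counts[3], minority) if M == "auto" else int(M)
    subsets = build_balanced_sets(train, majority_label=3, M=m, seed=seed, mode=subset_mode)
    coarse = fit_coarse(train, subsets, spec, alpha=alpha, meta_training=meta_training)
    refine_spec = BaseClassifierSpec(spec.method, dict(spec.hyperparameters), seed + m)
    refine = fit_refinement(train, refine_spec, balance=balance_refinement)
    return HierMCModel(
        coarse=coarse,
        refine=refine,
        schema_fingerprint=train.schema.fingerprint(),
        seeds={"subsets": seed, "base": seed, "refinement": seed + m},
        M=m,
    )


def predict_hier_mc(model: HierMCModel, rs: RecordSet) -> np.ndarray:
    """Two-step prediction: coarse labels first; records assigned to the
    combined class are routed through the refinement model, records
    labelled 3 are final."""
    if rs.schema.fingerprint() != model.schema_fingerprint:
        raise ValueError("record schema does not match the model's training schema")
    out = coarse_predict(model.coarse, rs)
    route = np.flatnonzero(out == COMBINED_45)
    if len(route):
        out = out.copy()
        out[route] = refine_predict(model.refine, rs.subset(route))
    return out


# ---------------------------------------------------------------------------
# Comparator strategies
# ---------------------------------------------------------------------------


@dataclass
class FlatModel:
    """A single multiclass classifier behind the shared predict contract."""

    estimator: object
    strategy: str
    spec: BaseClassifierSpec

    def predict(self, rs: RecordSet) -> np.ndarray:
        return self.estimator.predict(rs.features).astype(np.int64)


@dataclass
class SimpleMCStrategyModel:
    """The non-hierarchical meta-classifier behind the shared contract."""

    model: CoarseModel
    strategy: str = "simple_mc"

    def predict(self, rs: RecordSet) -> np.ndarray:
        return coarse_predict(self.model, rs)


def fit_comparator(
    train: RecordSet,
    strategy: str,
    spec: BaseClassifierSpec | None = None,
    seed: int | None = None,
    smote_k: int = 5,
    under_sampling_majority_only: bool = False,
):
    """Fit one of the comparison strategies on the 3-class training set.

    baseline_oaa
        One multiclass classifier with no imbalance handling. Inherently
        binary families (logistic regression) use a one-against-all
        decomposition; forests, naïve Bayes and trees are natively
        multiclass.
    under_sampling
        Every class randomly down-sampled without replacement to the
        smallest class size (``majority_only=True`` down-samples only
        stage 3 to the combined minority size), then one classifier.
    smote
        Minority classes over-sampled to the majority size by SMOTE: each
        synthetic record interpolates a minority record toward one of its
        k nearest within-class neighbours (Euclidean), then one classifier.
    simple_mc
        The non-hierarchical meta-classifier.
    hier_mc
        The hierarchical meta-classifier (for uniform harness access).
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"strategy must be one of {STRATEGIES}, got {strategy!r}")
    spec = spec or BaseClassifierSpec()
    seed = spec.seed if seed is None else seed
    spec = BaseClassifierSpec(spec.method, dict(spec.hyperparameters), seed)
    counts = train.class_counts()
    if min(counts.values()) == 0:
        raise ValueError(f"all three stages required for training, got {counts}")

    if strategy == "hier_mc":
        return fit_hier_mc(train, spec, seed=seed)
    if strategy == "simple_mc":
        return SimpleMCStrategyModel(fit_simple_meta_classifier(train, spec, seed=seed))

    if strategy == "baseline_oaa":
        X, y = train.features, train.stages
    elif strategy == "under_sampling":
        X, y = _under_sample(train, seed, majority_only=under_sampling_majority_only)
    else:  # smote
        X, y = _smote_oversample(
            train.features, train.stages, k=smote_k, seed=seed
        )

    est = make_estimator(spec, seed=seed)
    if spec.method == "logistic_regression":
        est = OneVsRestClassifier(est)
    est.fit(X, y)
    return FlatModel(est, strategy, spec)


def _under_sample(
    train: RecordSet, seed: int, majority_only: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    counts = train.class_counts()
    keep: list[np.ndarray] = []
    if majority_only:
        target = {3: counts[4] + counts[5], 4: counts[4], 5: counts[5]}
    else:
        smallest = min(counts.values())
        target = {s: smallest for s in STAGES}
    for s in STAGES:
        idx = np.flatnonzero(train.stages == s)
        if target[s] < len(idx):
            idx = rng.choice(idx, size=target[s], replace=False)
        keep.append(idx)
    rows = rng.permutation(np.concatenate(keep))
    return train.features[rows], train.stages[rows]


def _smote_oversample(
    X: np.ndarray, y: np.ndarray, k: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """SMOTE to the original published definition: for each synthetic
    point, pick a minority record x, one of its k nearest within-class
    neighbours x' (Euclidean), and emit x + u·(x'−x) with u ~ U(0,1)."""
    rng = np.random.default_rng(seed)
    classes, cls_counts = np.unique(y, return_counts=True)
    n_max = int(cls_counts.max())
    parts_X: list[np.ndarray] = [X]
    parts_y: list[np.ndarray] = [y]
    for cls, n_c in zip(classes, cls_counts):
        need = n_max - int(n_c)
        if need == 0:
            continue
        if n_c < k + 1:
            raise ValueError(
                f"class {cls} has {n_c} records, fewer than k+1={k + 1} needed "
                f"for SMOTE; use a smaller k"
            )
        Xc = X[y == cls]
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
        # column 0 is the point itself
        neigh = nn.kneighbors(Xc, return_distance=False)[:, 1:]
        base = rng.integers(0, len(Xc), size=need)
        pick = neigh[base, rng.integers(0, k, size=need)]
        u = rng.random((need, 1), dtype=np.float32)
        synth = Xc[base] + u * (Xc[pick] - Xc[base])
        parts_X.append(synth)
        parts_y.append(np.full(need, cls, dtype=y.dtype))
    # original rows first, synthetic rows appended per class
    return np.concatenate(parts_X), np.concatenate(parts_y)
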
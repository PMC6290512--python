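"""Synthetic imbalanced EHR-like cohort generator.

Emulates the documented structure of the study cohort so every downstream
stage (balancing, meta-classification, refinement, evaluation) is testable
without access to the private clinical data: ~23:2:1 record ratio across
stages 3/4/5, visit years 2007–2015 with 2015 held out, mean patient age 70
(SD 12), 60% female, ~17 visits per patient, 4 demographic + 4 vital + 447
binary diagnosed-condition features, and a ~22.8% incomplete-record rate.

Class signal is injected through a configurable number of "informative"
condition indicators whose odds are multiplied for the advanced stages, and
through mean shifts on the vital signs — enough structure for the imbalance
phenomenon (standard classifiers miss minority records; balanced ensembles
recover them) to be reproducible, with no pretence of modelling real
disease biology.

``study_replica`` instead *enforces* the published per-year, per-stage
record counts (features still synthetic) so that splitting and
partition-count logic can be validated against printed numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._study_counts import (
    DISEASE_INDICATOR_CONDITIONS,
    INCOMPLETE_RECORDS,
    N_PATIENTS,
    YEAR_STAGE_COUNTS,
)
from .data_model import STAGES, FeatureSchema, RecordSet

_CHUNK = 20_000  # rows per Bernoulli sampling block, bounds peak memory

_VITAL_BASE = (  # name, mean, sd
    ("heart_rate", 75.0, 12.0),
    ("systolic_bp", 130.0, 18.0),
    ("diastolic_bp", 80.0, 10.0),
    ("bmi", 29.0, 6.0),
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the documented study conditions; ``n_patients``
    scales the cohort (≈ ``n_patients × visits_mean`` records).
    """

    n_patients: int = 2000
    class_proportions: tuple[float, float, float] = (23 / 26, 2 / 26, 1 / 26)
    visits_mean: float = 17.0
    year_range: tuple[int, int] = (2007, 2015)
    n_condition_features: int = 447
    n_vital_features: int = 4
    n_demo_features: int = 4
    k_sep45: int = 30
    odds_mult_45: float = 4.0
    k_sep5: int = 15
    odds_mult_5: float = 3.0
    vital_shift: float = 0.8
    vital_shift_stage5_extra: float = 0.5
    missing_rate: float = 0.228
    include_flagged_features: bool = False
    n_medication_features: int = 33
    seed: int = 0

    def __post_init__(self) -> None:
        p = self.class_proportions
        if len(p) != 3 or any(x <= 0 for x in p) or not math.isclose(sum(p), 1.0):
            raise ValueError(
                "class_proportions must be three positive values summing to 1, "
                f"got {p}"
            )
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if self.k_sep45 + self.k_sep5 > self.n_condition_features:
            raise ValueError("k_sep45 + k_sep5 must not exceed n_condition_features")
        if self.visits_mean < 1:
            raise ValueError("visits_mean must be at least 1")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range must be increasing")


def default_schema(cfg: GeneratorConfig) -> FeatureSchema:
    """Schema matching the generator's feature layout.

    With ``include_flagged_features`` the schema additionally carries the
    seven disease-indicator conditions and the medication block, flagged for
    exclusion, mirroring the raw (pre-exclusion) study feature set.
    """
    names: list[str] = []
    cats: list[str] = []
    med: list[bool] = []
    ckd: list[bool] = []

    demo_names = ["age", "sex_female", "race_code", "ethnicity_code"]
    for i in range(cfg.n_demo_features):
        names.append(demo_names[i] if i < 4 else f"demo_{i + 1}")
        cats.append("demographics")
    for i in range(cfg.n_vital_features):
        names.append(_VITAL_BASE[i][0] if i < 4 else f"vital_{i + 1}")
        cats.append("vitals")
    for i in range(cfg.n_condition_features):
        names.append(f"cond_{i + 1:04d}")
        cats.append("condition")
    med = [False] * len(names)
    ckd = [False] * len(names)

    if cfg.include_flagged_features:
        for cname in DISEASE_INDICATOR_CONDITIONS:
            names.append(cname)
            cats.append("condition")
            med.append(False)
            ckd.append(True)
        for i in range(cfg.n_medication_features):
            names.append(f"med_{i + 1:02d}")
            cats.append("condition")
            med.append(True)
            ckd.append(False)

    return FeatureSchema(tuple(names), tuple(cats), tuple(med), tuple(ckd))


@dataclass
class _FeaturePlan:
    """Per-feature sampling parameters, drawn once per cohort."""

    cond_logits: np.ndarray  # (3, n_condition) class-conditional logits
    vital_means: np.ndarray  # (3, n_vitals)
    vital_sds: np.ndarray  # (n_vitals,)
    indicator_probs: np.ndarray | None  # (3, 7) flagged disease indicators
    med_logits: np.ndarray | None  # (3, n_medications)


def _build_plan(cfg: GeneratorConfig, rng: np.random.Generator) -> _FeaturePlan:
    nc = cfg.n_condition_features
    # long-tailed baseline prevalences, mimicking rare diagnosis codes
    base_p = 10 ** rng.uniform(np.log10(0.001), np.log10(0.2), size=nc)
    base_logit = np.log(base_p / (1 - base_p))
    logits = np.tile(base_logit, (3, 1))
    sep45 = slice(0, cfg.k_sep45)
    sep5 = slice(cfg.k_sep45, cfg.k_sep45 + cfg.k_sep5)
    logits[1, sep45] += np.log(cfg.odds_mult_45)  # stage 4
    logits[2, sep45] += np.log(cfg.odds_mult_45)  # stage 5
    logits[2, sep5] += np.log(cfg.odds_mult_5)  # stage 5 only

    nv = cfg.n_vital_features
    means = np.zeros((3, nv))
    sds = np.ones(nv)
    for i in range(nv):
        mu, sd = (_VITAL_BASE[i][1], _VITAL_BASE[i][2]) if i < 4 else (0.0, 1.0)
        means[:, i] = mu
        sds[i] = sd
    means[1] += cfg.vital_shift * sds
    means[2] += (cfg.vital_shift + cfg.vital_shift_stage5_extra) * sds

    ind_probs = None
    med_logits = None
    if cfg.include_flagged_features:
        # disease indicators are near-deterministic functions of the stage;
        # that is exactly why they are excluded from modelling
        ind_probs = np.full((3, len(DISEASE_INDICATOR_CONDITIONS)), 0.02)
        by_name = {n: j for j, n in enumerate(DISEASE_INDICATOR_CONDITIONS)}
        ind_probs[0, by_name["CKD stage 3"]] = 0.85
        ind_probs[1, by_name["CKD stage 4"]] = 0.85
        ind_probs[2, by_name["End Stage Renal Disease"]] = 0.70
        ind_probs[2, by_name["Renal Failure Syndrome"]] = 0.50
        ind_probs[1:, by_name["Chronic Renal Failure"]] = 0.40
        ind_probs[2, by_name["History of renal transplant (situation)"]] = 0.10
        ind_probs[:, by_name["CKD stage 2"]] = 0.05
        mp = 10 ** rng.uniform(np.log10(0.005), np.log10(0.3), cfg.n_medication_features)
        med_logits = np.tile(np.log(mp / (1 - mp)), (3, 1))
        med_logits[1:] += np.log(2.5)  # advanced stages carry more prescriptions
    return _FeaturePlan(logits, means, sds, ind_probs, med_logits)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _sample_features(
    cfg: GeneratorConfig,
    plan: _FeaturePlan,
    rng: np.random.Generator,
    stage_idx: np.ndarray,
    demo: np.ndarray,
) -> np.ndarray:
    """Assemble the full (n, D) feature matrix for records with the given
    per-record stage index (0/1/2) and demographic block."""
    n = len(stage_idx)
    nv = cfg.n_vital_features
    vitals = (
        plan.vital_means[stage_idx]
        + rng.standard_normal((n, nv)) * plan.vital_sds[None, :]
    )
    blocks = [demo.astype(np.float32), vitals.astype(np.float32)]

    cond_p = _sigmoid(plan.cond_logits)
    blocks.append(_bernoulli_by_class(rng, cond_p, stage_idx))
    if plan.indicator_probs is not None:
        blocks.append(_bernoulli_by_class(rng, plan.indicator_probs, stage_idx))
    if plan.med_logits is not None:
        blocks.append(_bernoulli_by_class(rng, _sigmoid(plan.med_logits), stage_idx))
    return np.hstack(blocks)


def _bernoulli_by_class(
    rng: np.random.Generator, probs: np.ndarray, stage_idx: np.ndarray
) -> np.ndarray:
    """Chunked class-conditional Bernoulli draws as float32 0/1."""
    n, f = len(stage_idx), probs.shape[1]
    out = np.empty((n, f), dtype=np.float32)
    for lo in range(0, n, _CHUNK):
        hi = min(lo + _CHUNK, n)
        u = rng.random((hi - lo, f))
        out[lo:hi] = (u < probs[stage_idx[lo:hi]]).astype(np.float32)
    return out


def _sample_demographics(
    cfg: GeneratorConfig, rng: np.random.Generator, n_patients: int
) -> np.ndarray:
    """Per-patient demographic block: age ~ N(70, 12) truncated to
    [18, 100], 60% female, categorical race/ethnicity codes."""
    cols = []
    a, b = (18 - 70) / 12, (100 - 70) / 12
    age = stats.truncnorm.rvs(a, b, loc=70, scale=12, size=n_patients, random_state=rng)
    cols.append(age)
    if cfg.n_demo_features >= 2:
        cols.append((rng.random(n_patients) < 0.60).astype(float))
    if cfg.n_demo_features >= 3:
        cols.append(rng.choice(4, size=n_patients, p=[0.70, 0.15, 0.10, 0.05]).astype(float))
    if cfg.n_demo_features >= 4:
        cols.append(rng.choice(2, size=n_patients, p=[0.85, 0.15]).astype(float))
    for _ in range(cfg.n_demo_features - 4):
        cols.append(rng.standard_normal(n_patients))
    return np.column_stack(cols[: cfg.n_demo_features])


def _inject_missing(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    features: np.ndarray,
    schema: FeatureSchema,
    rows: np.ndarray,
) -> np.ndarray:
    """Blank 1–3 pertinent (retained) cells in each of ``rows``; returns the
    missing mask. Missing cells are NaN in the feature matrix."""
    mask = np.zeros(features.shape, dtype=bool)
    pertinent = np.flatnonzero(~schema.excluded)
    for i in rows:
        k = int(rng.integers(1, 4))
        cols = rng.choice(pertinent, size=min(k, len(pertinent)), replace=False)
        mask[i, cols] = True
        features[i, cols] = np.nan
    return mask


def generate_cohort(cfg: GeneratorConfig) -> RecordSet:
    """Generate a longitudinal imbalanced cohort, reproducible from
    ``cfg.seed``.

    Each patient receives a visit count ~ 1 + Poisson(visits_mean − 1) and
    visit years uniform over a random active span within ``year_range``;
    each record is independently assigned a stage from
    ``class_proportions`` (record-level control of the imbalance ratio).
    """
    rng = np.random.default_rng(cfg.seed)
    schema = default_schema(cfg)
    plan = _build_plan(cfg, rng)

    npat = cfg.n_patients
    demo_pat = _sample_demographics(cfg, rng, npat)
    visits = 1 + rng.poisson(cfg.visits_mean - 1, size=npat)
    y0, y1 = cfg.year_range
    span_a = rng.integers(y0, y1 + 1, size=npat)
    span_b = rng.integers(y0, y1 + 1, size=npat)
    starts, ends = np.minimum(span_a, span_b), np.maximum(span_a, span_b)

    n = int(visits.sum())
    pat_of_rec = np.repeat(np.arange(npat), visits)
    u = rng.random(n)
    lo = starts[pat_of_rec]
    width = ends[pat_of_rec] - lo + 1
    years = lo + np.floor(u * width).astype(np.int64)

    stage_idx = rng.choice(3, size=n, p=np.asarray(cfg.class_proportions))
    stages = np.asarray(STAGES)[stage_idx]

    features = _sample_features(cfg, plan, rng, stage_idx, demo_pat[pat_of_rec])
    miss_rows = np.flatnonzero(rng.random(n) < cfg.missing_rate)
    mask = _inject_missing(cfg, rng, features, schema, miss_rows)

    ids = np.array([f"P{p + 1:06d}" for p in pat_of_rec], dtype=object)
    return RecordSet(
        schema=schema,
        patient_ids=ids,
        visit_years=years,
        stages=stages,
        features=features,
        missing_mask=mask,
    )


def study_replica(cfg: GeneratorConfig | None = None, include_incomplete: bool = True) -> RecordSet:
    """Cohort whose per-year, per-stage *complete*-record counts equal the
    published study distribution exactly (features remain synthetic).

    With ``include_incomplete`` the documented number of incomplete records
    is added (allocated across year×stage cells by largest-remainder
    proportional rounding, each with at least one blanked pertinent value),
    so complete-case filtering recovers the published complete count.
    """
    cfg = cfg or GeneratorConfig()
    if tuple(cfg.year_range) != (2007, 2015):
        raise ValueError(
            f"study replica requires year_range (2007, 2015), got {cfg.year_range}"
        )
    rng = np.random.default_rng(cfg.seed)
    schema = default_schema(cfg)
    plan = _build_plan(cfg, rng)

    years_l: list[np.ndarray] = []
    stage_idx_l: list[np.ndarray] = []
    complete_counts: list[int] = []
    for year, counts in sorted(YEAR_STAGE_COUNTS.items()):
        for s_idx, c in enumerate(counts):
            years_l.append(np.full(c, year, dtype=np.int64))
            stage_idx_l.append(np.full(c, s_idx, dtype=np.int64))
            complete_counts.append(c)

    if include_incomplete:
        extra = _largest_remainder_allocation(
            np.asarray(complete_counts, dtype=float), INCOMPLETE_RECORDS
        )
        i = 0
        incomplete_l: list[np.ndarray] = []
        for year, counts in sorted(YEAR_STAGE_COUNTS.items()):
            for s_idx in range(3):
                e = extra[i]
                years_l.append(np.full(e, year, dtype=np.int64))
                stage_idx_l.append(np.full(e, s_idx, dtype=np.int64))
                incomplete_l.append(np.ones(e, dtype=bool))
                i += 1
        n_complete = sum(complete_counts)
        incomplete_flag = np.concatenate(
            [np.zeros(n_complete, dtype=bool)] + incomplete_l
        )
    else:
        incomplete_flag = np.zeros(sum(complete_counts), dtype=bool)

    years = np.concatenate(years_l)
    stage_idx = np.concatenate(stage_idx_l)
    n = len(years)

    demo_pat = _sample_demographics(cfg, rng, N_PATIENTS)
    pat_of_rec = rng.integers(0, N_PATIENTS, size=n)
    features = _sample_features(cfg, plan, rng, stage_idx, demo_pat[pat_of_rec])
    mask = _inject_missing(cfg, rng, features, schema, np.flatnonzero(incomplete_flag))

    ids = np.array([f"P{p + 1:06d}" for p in pat_of_rec], dtype=object)
    return RecordSet(
        schema=schema,
        patient_ids=ids,
        visit_years=years,
        stages=np.asarray(STAGES)[stage_idx],
        features=features,
        missing_mask=mask,
    )


def _largest_remainder_allocation(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights`` that sums
    exactly to ``total`` (largest-remainder / Hamilton rounding)."""
    quota = weights / weights.sum() * total
    base = np.floor(quota).astype(int)
    short = total - int(base.sum())
    if short:
        order = np.argsort(-(quota - base))
        base[order[:short]] += 1
    return base
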
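import numpy as np
import pytest
from hypothesis import settings

from hiermc import (
    BaseClassifierSpec,
    FeatureSchema,
    GeneratorConfig,
    RecordSet,
    complete_case_filter,
    generate_cohort,
    study_replica,
    temporal_split,
)

settings.register_profile("suite", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("suite")


def make_recordset(
    stages,
    years=None,
    n_features=6,
    seed=0,
    patient_ids=None,
    schema=None,
):
    """Small hand-controllable RecordSet for unit tests."""
    rng = np.random.default_rng(seed)
    stages = np.asarray(stages)
    n = len(stages)
    schema = schema or FeatureSchema(
        names=tuple(f"f{i}" for i in range(n_features)),
        categories=("demographics",) * min(1, n_features)
        + ("vitals",) * min(1, max(0, n_features - 1))
        + ("condition",) * max(0, n_features - 2),
    )
    return RecordSet(
        schema=schema,
        patient_ids=np.asarray(
            patient_ids if patient_ids is not None else [f"P{i}" for i in range(n)],
            dtype=object,
        ),
        visit_years=np.asarray(years if years is not None else [2010] * n),
        stages=stages,
        features=rng.random((n, len(schema)), dtype=np.float32),
        missing_mask=np.zeros((n, len(schema)), dtype=bool),
    )


def separable_recordset(n3=60, n4=20, n5=10, years=None, seed=0, noise=0.05):
    """Three-class set with well-separated class means on a few features."""
    rng = np.random.default_rng(seed)
    stages = np.concatenate([[3] * n3, [4] * n4, [5] * n5])
    n = len(stages)
    centers = {3: (0.0, 0.0), 4: (3.0, 0.0), 5: (3.0, 3.0)}
    feats = rng.normal(scale=noise, size=(n, 4)).astype(np.float32)
    for i, s in enumerate(stages):
        feats[i, 0] += centers[s][0]
        feats[i, 1] += centers[s][1]
    schema = FeatureSchema(
        names=("x1", "x2", "x3", "x4"),
        categories=("vitals",) * 4,
    )
    if years is None:
        years = rng.integers(2007, 2015, size=n)
    return RecordSet(
        schema=schema,
        patient_ids=np.asarray([f"P{i}" for i in range(n)], dtype=object),
        visit_years=np.asarray(years),
        stages=stages,
        features=feats,
        missing_mask=np.zeros((n, 4), dtype=bool),
    )


@pytest.fixture(scope="session")
def fast_spec():
    """Small random forest: keeps ensemble unit tests quick."""
    return BaseClassifierSpec(hyperparameters={"n_estimators": 15}, seed=0)


@pytest.fixture(scope="session")
def small_cohort():
    """Prepared (complete-case) synthetic cohort of ~5k records."""
    rs = generate_cohort(GeneratorConfig(n_patients=300, seed=1))
    return complete_case_filter(rs)


@pytest.fixture(scope="session")
def small_split(small_cohort):
    return temporal_split(small_cohort, 2007, 2014, 2015)


@pytest.fixture(scope="session")
def replica():
    """Full-scale replica of the published cohort distribution (session
    scoped: generation is seconds but the table is ~120k x 455)."""
    return study_replica(GeneratorConfig(seed=7))
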
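"""Domain types and tabular I/O for visit-record cohorts.

A cohort is a flat table of office-visit records: one row per visit with a
patient identifier, a calendar visit year, a fixed-length numeric feature
vector (demographics + vital signs + binary diagnosed-condition indicators)
and a disease-stage label in {3, 4, 5}. Missing feature values are encoded
as empty cells on disk and as NaN plus an explicit boolean mask in memory.

The module also owns the cohort-preparation rules used throughout the
package: dropping medication and disease-indicator features, complete-case
filtering on the retained ("pertinent") features, and temporal train/test
splitting by calendar year.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

#: Valid disease-stage labels carried by individual records.
STAGES = (3, 4, 5)

#: Token for the combined minority class (stages 4 and 5 pooled) used by the
#: coarse classification step. Deliberately distinct from both 4 and 5.
COMBINED_45 = 45

#: Feature categories recognised by the schema.
CATEGORIES = ("demographics", "vitals", "condition")

_META_COLUMNS = ("patient_id", "visit_year", "stage")


class SchemaError(ValueError):
    """Raised when a schema is internally inconsistent or mismatched."""


class RecordParseError(ValueError):
    """Raised when a record file cannot be parsed; names the offending row."""


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered description of the feature columns of a cohort table.

    Parameters
    ----------
    names : unique feature identifiers, in column order.
    categories : one of ``demographics`` / ``vitals`` / ``condition`` per
        feature.
    is_medication : flags features describing prescribed medications, which
        are excluded from modelling (indicative of a diagnosis rather than
        predictive of it).
    is_ckd_indicator : flags diagnosed-condition features that directly name
        the disease being staged, excluded for the same reason.
    """

    names: tuple[str, ...]
    categories: tuple[str, ...]
    is_medication: tuple[bool, ...] = ()
    is_ckd_indicator: tuple[bool, ...] = ()

    def __post_init__(self) -> None:
        n = len(self.names)
        if len(set(self.names)) != n:
            raise SchemaError("feature names must be unique")
        if len(self.categories) != n:
            raise SchemaError("categories must match names in length")
        bad = sorted(set(self.categories) - set(CATEGORIES))
        if bad:
            raise SchemaError(f"unknown feature categories: {bad}")
        for attr in ("is_medication", "is_ckd_indicator"):
            flags = getattr(self, attr)
            if len(flags) == 0:
                object.__setattr__(self, attr, (False,) * n)
            elif len(flags) != n:
                raise SchemaError(f"{attr} must match names in length")

    def __len__(self) -> int:
        return len(self.names)

    @property
    def excluded(self) -> np.ndarray:
        """Boolean array marking features dropped by the exclusion rules."""
        return np.asarray(self.is_medication) | np.asarray(self.is_ckd_indicator)

    def apply_exclusions(self) -> "FeatureSchema":
        keep = ~self.excluded
        return FeatureSchema(
            names=tuple(np.asarray(self.names)[keep]),
            categories=tuple(np.asarray(self.categories)[keep]),
        )

    def fingerprint(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for name, cat in zip(self.names, self.categories):
            h.update(name.encode())
            h.update(cat.encode())
        return h.hexdigest()[:16]


@dataclass(frozen=True)
class VisitRecord:
    """A single office visit: identifier, year, features and stage label."""

    patient_id: str
    visit_year: int
    features: np.ndarray
    stage: int
    missing_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {self.stage}")
        if self.features.shape != self.missing_mask.shape:
            raise ValueError("features and missing_mask must have equal length")


@dataclass
class RecordSet:
    """An ordered collection of visit records sharing one feature schema.

    Stored column-wise (arrays over records) for efficiency; ``record(i)``
    materialises a single :class:`VisitRecord` view when needed.
    """

    schema: FeatureSchema
    patient_ids: np.ndarray
    visit_years: np.ndarray
    stages: np.ndarray
    features: np.ndarray
    missing_mask: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.patient_ids)
        d = len(self.schema)
        self.patient_ids = np.asarray(self.patient_ids, dtype=object)
        self.visit_years = np.asarray(self.visit_years, dtype=np.int64)
        self.stages = np.asarray(self.stages, dtype=np.int64)
        self.features = np.asarray(self.features, dtype=np.float32).reshape(n, d)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool).reshape(n, d)
        for arr, name in ((self.visit_years, "visit_years"), (self.stages, "stages")):
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per record")
        bad = set(np.unique(self.stages)) - set(STAGES)
        if len(self.stages) and bad:
            raise ValueError(f"invalid stage labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.patient_ids)

    def record(self, i: int) -> VisitRecord:
        return VisitRecord(
            patient_id=str(self.patient_ids[i]),
            visit_year=int(self.visit_years[i]),
            features=self.features[i],
            stage=int(self.stages[i]),
            missing_mask=self.missing_mask[i],
        )

    def subset(self, index: np.ndarray | Sequence[int]) -> "RecordSet":
        """A new RecordSet containing the rows of ``index``, in that order."""
        idx = np.asarray(index)
        if idx.dtype != bool:
            idx = idx.astype(np.int64, copy=False)
        return RecordSet(
            schema=self.schema,
            patient_ids=self.patient_ids[idx],
            visit_years=self.visit_years[idx],
            stages=self.stages[idx],
            features=self.features[idx],
            missing_mask=self.missing_mask[idx],
        )

    def class_counts(self) -> dict[int, int]:
        return class_counts(self)

    @staticmethod
    def empty(schema: FeatureSchema) -> "RecordSet":
        d = len(schema)
        return RecordSet(
            schema=schema,
            patient_ids=np.empty(0, dtype=object),
            visit_years=np.empty(0, dtype=np.int64),
            stages=np.empty(0, dtype=np.int64),
            features=np.empty((0, d), dtype=np.float32),
            missing_mask=np.empty((0, d), dtype=bool),
        )


@dataclass(frozen=True)
class TemporalSplit:
    """Chronological train/test partition: train years strictly precede the
    single held-out test year, emulating prospective prediction."""

    train: RecordSet
    test: RecordSet
    train_years: tuple[int, int]
    test_year: int


# ---------------------------------------------------------------------------
# Schema sidecar I/O
# ---------------------------------------------------------------------------


def write_schema(schema: FeatureSchema, path: str | Path) -> None:
    """Write the schema sidecar as YAML: one entry per feature with its
    category and exclusion flags."""
    entries = [
        {
            "name": name,
            "category": cat,
            "is_medication": bool(med),
            "is_ckd_indicator": bool(ckd),
        }
        for name, cat, med, ckd in zip(
            schema.names, schema.categories, schema.is_medication, schema.is_ckd_indicator
        )
    ]
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({"features": entries}, fh, sort_keys=False)


def read_schema(path: str | Path) -> FeatureSchema:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    try:
        entries = doc["features"]
    except (TypeError, KeyError):
        raise SchemaError(f"{path}: expected a top-level 'features' list")
    return FeatureSchema(
        names=tuple(e["name"] for e in entries),
        categories=tuple(e["category"] for e in entries),
        is_medication=tuple(bool(e.get("is_medication", False)) for e in entries),
        is_ckd_indicator=tuple(bool(e.get("is_ckd_indicator", False)) for e in entries),
    )


# ---------------------------------------------------------------------------
# Record table I/O (CSV, UTF-8, header mandatory, empty cell == missing)
# ---------------------------------------------------------------------------


def write_records(rs: RecordSet, path: str | Path) -> None:
    """Write a RecordSet as CSV.

    Column order is ``patient_id, visit_year, stage`` followed by the schema
    feature names; missing values become empty cells. Output is
    deterministic for a given RecordSet.
    """
    feat = rs.features.astype(np.float64).copy()
    feat[rs.missing_mask] = np.nan
    cols: dict[str, object] = {
        "patient_id": rs.patient_ids.astype(str),
        "visit_year": rs.visit_years,
        "stage": rs.stages,
    }
    cols.update({name: feat[:, j] for j, name in enumerate(rs.schema.names)})
    pd.DataFrame(cols).to_csv(path, index=False, na_rep="")


def read_records(path: str | Path, schema: FeatureSchema) -> RecordSet:
    """Read a CSV record table against ``schema``.

    Raises :class:`RecordParseError` naming the 1-based data row for any
    malformed value, and :class:`SchemaError` if the header does not carry
    exactly the expected columns in order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path, dtype=str, keep_default_na=False, na_values=[], encoding="utf-8"
    )
    expected = list(_META_COLUMNS) + list(schema.names)
    if list(df.columns) != expected:
        raise SchemaError(
            f"{path}: header does not match schema "
            f"(expected {len(expected)} columns starting {expected[:4]}..., "
            f"got {len(df.columns)} starting {list(df.columns)[:4]}...)"
        )
    n = len(df)
    d = len(schema)

    years = _parse_int_column(df["visit_year"], "visit_year")
    stage_vals = _parse_int_column(df["stage"], "stage")
    bad = ~np.isin(stage_vals, STAGES)
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 1
        raise RecordParseError(
            f"row {row}: unknown stage value {stage_vals[bad][0]!r} "
            f"(expected one of {STAGES})"
        )

    features = np.empty((n, d), dtype=np.float32)
    mask = np.zeros((n, d), dtype=bool)
    for j, name in enumerate(schema.names):
        raw = df[name].to_numpy()
        empty = raw == ""
        vals = pd.to_numeric(pd.Series(np.where(empty, "nan", raw)), errors="coerce")
        bad_cells = vals.isna().to_numpy() & ~empty
        if bad_cells.any():
            row = int(np.flatnonzero(bad_cells)[0]) + 1
            raise RecordParseError(
                f"row {row}: malformed value {raw[bad_cells][0]!r} "
                f"in feature column {name!r}"
            )
        col = vals.to_numpy(dtype=np.float64)
        col[empty] = np.nan
        features[:, j] = col
        mask[:, j] = empty
    return RecordSet(
        schema=schema,
        patient_ids=df["patient_id"].to_numpy(dtype=object),
        visit_years=years,
        stages=stage_vals,
        features=features,
        missing_mask=mask,
    )


def _parse_int_column(col: pd.Series, name: str) -> np.ndarray:
    vals = pd.to_numeric(col, errors="coerce")
    bad = vals.isna().to_numpy()
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 1
        raise RecordParseError(
            f"row {row}: malformed value {col.iloc[row - 1]!r} in column {name!r}"
        )
    return vals.to_numpy(dtype=np.int64)


# ---------------------------------------------------------------------------
# Cohort preparation
# ---------------------------------------------------------------------------


def apply_feature_exclusions(rs: RecordSet) -> RecordSet:
    """Drop every medication and disease-indicator feature.

    Record count is unchanged; feature vectors and the missing mask are
    sliced to the retained columns. With no flagged features this is the
    identity.
    """
    keep = ~rs.schema.excluded
    if keep.all():
        return rs
    return RecordSet(
        schema=rs.schema.apply_exclusions(),
        patient_ids=rs.patient_ids,
        visit_years=rs.visit_years,
        stages=rs.stages,
        features=rs.features[:, keep],
        missing_mask=rs.missing_mask[:, keep],
    )


def complete_case_filter(rs: RecordSet) -> RecordSet:
    """Retain only records with no missing value on any retained feature.

    Missingness is judged on the features currently in the schema (the
    "pertinent" attributes); order of the surviving records is preserved.
    """
    complete = ~rs.missing_mask.any(axis=1)
    if complete.all():
        return rs
    return rs.subset(np.flatnonzero(complete))


def temporal_split(
    rs: RecordSet, first_train_year: int, last_train_year: int, test_year: int
) -> TemporalSplit:
    """Split chronologically: train on [first, last] train years, test on a
    single later year. Records outside both ranges are dropped."""
    if not (first_train_year <= last_train_year < test_year):
        raise ValueError(
            "require first_train_year <= last_train_year < test_year, got "
            f"{first_train_year}, {last_train_year}, {test_year}"
        )
    years = rs.visit_years
    train_idx = np.flatnonzero((years >= first_train_year) & (years <= last_train_year))
    test_idx = np.flatnonzero(years == test_year)
    return TemporalSplit(
        train=rs.subset(train_idx),
        test=rs.subset(test_idx),
        train_years=(first_train_year, last_train_year),
        test_year=test_year,
    )


def class_counts(rs: RecordSet) -> dict[int, int]:
    """Records per stage; absent stages are reported as 0."""
    counts = {int(s): 0 for s in STAGES}
    vals, cnts = np.unique(rs.stages, return_counts=True)
    for v, c in zip(vals, cnts):
        counts[int(v)] = int(c)
    return counts
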
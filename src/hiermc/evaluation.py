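"""Per-class evaluation metrics and multi-run experiment protocols.

Metrics follow the one-vs-rest convention: for each stage i, TP_i are
stage-i records assigned to stage i, TN_i records of other stages not
assigned to i, FP_i other-stage records misassigned to i, and FN_i stage-i
records assigned elsewhere. Derived measures:

    specificity = TN/(TN+FP)     sensitivity (TPR, recall) = TP/(TP+FN)
    precision (PPV) = TP/(TP+FP) F-measure = 2·P·S/(P+S)

A 0/0 denominator yields 0 with a logged warning — conservative and keeps
aggregates defined on tiny test sets. "Average" metrics are the unweighted
macro mean over the three stages; experiment protocols report mean and
standard deviation over seeded repeats against a fixed test set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import STAGES, RecordSet, TemporalSplit, temporal_split
from .meta import BaseClassifierSpec
from .pipeline import fit_comparator

logger = logging.getLogger(__name__)

METRIC_NAMES = ("specificity", "sensitivity", "precision", "f_measure")


@dataclass(frozen=True)
class ClassMetrics:
    """One-vs-rest counts and derived metrics for a single class."""

    label: int
    tp: int
    tn: int
    fp: int
    fn: int
    specificity: float
    sensitivity: float
    precision: float
    f_measure: float

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_counts(
    true_labels: Sequence[int], predicted_labels: Sequence[int], class_of_interest: int
) -> tuple[int, int, int, int]:
    """One-vs-rest (TP, TN, FP, FN) for the class of interest."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError(
            f"label sequences differ in length: {t.shape} vs {p.shape}"
        )
    t_pos = t == class_of_interest
    p_pos = p == class_of_interest
    tp = int(np.sum(t_pos & p_pos))
    tn = int(np.sum(~t_pos & ~p_pos))
    fp = int(np.sum(~t_pos & p_pos))
    fn = int(np.sum(t_pos & ~p_pos))
    return tp, tn, fp, fn


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("0/0 in %s; reporting 0.0", name)
        return 0.0
    return num / den


def compute_metrics(counts: tuple[int, int, int, int]) -> tuple[float, float, float, float]:
    """(specificity, sensitivity, precision, F-measure) from (TP, TN, FP, FN)."""
    tp, tn, fp, fn = counts
    if min(counts) < 0:
        raise ValueError("confusion counts must be nonnegative")
    spec = _safe_ratio(tn, tn + fp, "specificity")
    sens = _safe_ratio(tp, tp + fn, "sensitivity")
    prec = _safe_ratio(tp, tp + fp, "precision")
    f = _safe_ratio(2 * prec * sens, prec + sens, "f_measure")
    return spec, sens, prec, f


def class_metrics(
    true_labels: Sequence[int], predicted_labels: Sequence[int], label: int
) -> ClassMetrics:
    tp, tn, fp, fn = confusion_counts(true_labels, predicted_labels, label)
    spec, sens, prec, f = compute_metrics((tp, tn, fp, fn))
    return ClassMetrics(label, tp, tn, fp, fn, spec, sens, prec, f)


def evaluate_labels(
    true_labels: Sequence[int],
    predicted_labels: Sequence[int],
    classes: Sequence[int] = STAGES,
    include_combined: bool = False,
) -> dict[int, ClassMetrics]:
    """Per-class metrics; with ``include_combined`` an extra entry keyed
    45 treats stages 4 and 5 as one pooled positive class."""
    out = {int(c): class_metrics(true_labels, predicted_labels, c) for c in classes}
    if include_combined:
        t = np.asarray(true_labels)
        p = np.asarray(predicted_labels)
        t45 = np.where(np.isin(t, (4, 5)), 45, t)
        p45 = np.where(np.isin(p, (4, 5)), 45, p)
        out[45] = class_metrics(t45, p45, 45)
    return out


def macro_average(per_class: Mapping[int, ClassMetrics]) -> dict[str, float]:
    """Unweighted mean of each metric over the three stages."""
    missing = [s for s in STAGES if s not in per_class]
    if missing:
        raise ValueError(f"macro average requires all stages; missing {missing}")
    return {
        m: float(np.mean([getattr(per_class[s], m) for s in STAGES]))
        for m in METRIC_NAMES
    }


@dataclass
class ExperimentResult:
    """Tidy per-run metric table plus aggregation helpers.

    ``per_run`` has one row per (strategy, window, repeat, class) with the
    four counts and four metrics; ``class`` is a stage or ``"macro"``.
    """

    per_run: pd.DataFrame
    repeats: int
    base_seed: int
    record_counts: dict[str, dict[int, int]]

    def summary(self) -> pd.DataFrame:
        """Mean (and, when repeats ≥ 2, standard deviation) of each metric
        grouped by strategy, window and class."""
        keys = ["strategy", "window", "class"]
        g = self.per_run.groupby(keys)[list(METRIC_NAMES)]
        mean = g.mean()
        if self.repeats >= 2:
            std = g.std(ddof=1)
            out = mean.join(std, lsuffix="_mean", rsuffix="_std")
        else:
            out = mean.add_suffix("_mean")
        return out.reset_index()

    def tpr_table(self) -> pd.DataFrame:
        """Per-window, per-stage mean sensitivity (the truncation-curve
        analogue): one row per stage per window."""
        rows = self.per_run[self.per_run["class"].isin([str(s) for s in STAGES])]
        return (
            rows.groupby(["strategy", "window", "class"])["sensitivity"]
            .mean()
            .reset_index()
            .rename(columns={"class": "stage", "sensitivity": "tpr"})
        )


def _run_rows(
    strategy: str,
    window: str,
    repeat: int,
    true_labels: np.ndarray,
    predicted: np.ndarray,
) -> list[dict]:
    per_class = evaluate_labels(true_labels, predicted)
    rows = []
    for s in STAGES:
        cm = per_class[s]
        rows.append(
            {
                "strategy": strategy,
                "window": window,
                "repeat": repeat,
                "class": str(s),
                "tp": cm.tp,
                "tn": cm.tn,
                "fp": cm.fp,
                "fn": cm.fn,
                "specificity": cm.specificity,
                "sensitivity": cm.sensitivity,
                "precision": cm.precision,
                "f_measure": cm.f_measure,
            }
        )
    macro = macro_average(per_class)
    rows.append(
        {
            "strategy": strategy,
            "window": window,
            "repeat": repeat,
            "class": "macro",
            "tp": np.nan,
            "tn": np.nan,
            "fp": np.nan,
            "fn": np.nan,
            **macro,
        }
    )
    return rows


def run_comparison(
    split: TemporalSplit,
    strategies: Sequence[str],
    spec: BaseClassifierSpec | None = None,
    repeats: int = 1,
    base_seed: int = 0,
    window_label: str | None = None,
    **strategy_kwargs,
) -> ExperimentResult:
    """Head-to-head strategy comparison on one temporal split.

    Each strategy is refit ``repeats`` times with seed ``base_seed + r``
    (re-drawing balanced subsets and re-seeding the classifiers); the test
    set is fixed across repeats and strategies.
    """
    if repeats < 1:
        raise ValueError("repeats must be at least 1")
    if len(split.test) == 0:
        raise ValueError("test set is empty; evaluation is undefined")
    spec = spec or BaseClassifierSpec()
    window = window_label or f"{split.train_years[0]}-{split.train_years[1]}"
    rows: list[dict] = []
    for strategy in strategies:
        for r in range(repeats):
            model = fit_comparator(
                split.train,
                strategy,
                spec=spec,
                seed=base_seed + r,
                **strategy_kwargs,
            )
            predicted = model.predict(split.test)
            rows.extend(_run_rows(strategy, window, r, split.test.stages, predicted))
            logger.info(
                "strategy=%s window=%s repeat=%d seed=%d done",
                strategy,
                window,
                r,
                base_seed + r,
            )
    counts = {
        "train": split.train.class_counts(),
        "test": split.test.class_counts(),
    }
    return ExperimentResult(
        per_run=pd.DataFrame(rows),
        repeats=repeats,
        base_seed=base_seed,
        record_counts=counts,
    )


def run_truncation_experiment(
    rs: RecordSet,
    windows: Sequence[tuple[int, int]],
    test_year: int,
    strategy: str = "hier_mc",
    spec: BaseClassifierSpec | None = None,
    repeats: int = 1,
    base_seed: int = 0,
    **strategy_kwargs,
) -> ExperimentResult:
    """Training-history truncation protocol: one full comparison per year
    window against the fixed held-out test year; emits the per-window
    per-stage TPR table via ``ExperimentResult.tpr_table``."""
    if not windows:
        raise ValueError("windows must be nonempty")
    frames: list[pd.DataFrame] = []
    counts: dict[str, dict[int, int]] = {}
    for first, last in windows:
        split = temporal_split(rs, first, last, test_year)
        if len(split.train) == 0:
            raise ValueError(f"training window {first}-{last} contains no records")
        res = run_comparison(
            split,
            [strategy],
            spec=spec,
            repeats=repeats,
            base_seed=base_seed,
            window_label=f"{first}-{last}",
            **strategy_kwargs,
        )
        frames.append(res.per_run)
        counts[f"{first}-{last}"] = split.train.class_counts()
    counts["test"] = split.test.class_counts()
    return ExperimentResult(
        per_run=pd.concat(frames, ignore_index=True),
        repeats=repeats,
        base_seed=base_seed,
        record_counts=counts,
    )
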
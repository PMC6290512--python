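"""Balanced majority-class partitioning.

The coarse classification step trains an ensemble of M base-classifiers,
each on a balanced two-class set: one disjoint block of majority-class
(stage 3) records, the size of the entire combined minority class (stages
4 and 5), paired with that full minority set. M defaults to the floor of
the majority:minority ratio, so (almost) every majority record is used by
exactly one base-classifier and no synthetic records are fabricated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import RecordSet


@dataclass
class BalancedSubsets:
    """The M balanced training sets plus bookkeeping for invariant checks.

    ``majority_blocks`` holds the disjoint majority-row indices (into the
    originating RecordSet) behind each subset; ``leftover`` the unused
    majority rows.
    """

    subsets: list[RecordSet]
    M: int
    minority_size: int
    seed: int
    majority_blocks: list[np.ndarray]
    minority_index: np.ndarray
    leftover: np.ndarray
    mode: str


def compute_num_partitions(majority_count: int, minority_count: int) -> int:
    """Number of balanced partitions: floor(majority / minority), at least 1."""
    if minority_count <= 0:
        raise ValueError("minority class is empty; cannot derive partition count")
    if majority_count < minority_count:
        raise ValueError(
            "majority class smaller than minority class "
            f"({majority_count} < {minority_count})"
        )
    return max(1, majority_count // minority_count)


def build_balanced_sets(
    train: RecordSet,
    majority_label: int,
    M: int,
    seed: int,
    mode: str = "partition",
) -> BalancedSubsets:
    """Build M balanced two-class training sets.

    ``partition`` mode (default): the majority rows are shuffled once and
    chunked into M disjoint blocks of minority size; leftover majority rows
    are unused by the base-classifiers. ``resample`` mode draws each block
    independently without replacement instead, so blocks may overlap across
    subsets. Every subset pairs its block with the complete minority set
    and is shuffled before return.
    """
    if M < 1:
        raise ValueError("M must be at least 1")
    if mode not in ("partition", "resample"):
        raise ValueError(f"unknown mode {mode!r}")
    stages = train.stages
    majority_idx = np.flatnonzero(stages == majority_label)
    minority_idx = np.flatnonzero(stages != majority_label)
    m_size = len(minority_idx)
    if m_size == 0:
        raise ValueError("minority class is empty")
    needed = M * m_size
    if mode == "partition" and len(majority_idx) < needed:
        raise ValueError(
            f"insufficient majority records for {M} disjoint blocks of "
            f"{m_size}: have {len(majority_idx)}, need {needed} "
            f"(short by {needed - len(majority_idx)})"
        )
    if mode == "resample" and len(majority_idx) < m_size:
        raise ValueError(
            f"majority class ({len(majority_idx)}) smaller than minority "
            f"({m_size}); cannot sample without replacement"
        )

    rng = np.random.default_rng(seed)
    blocks: list[np.ndarray] = []
    if mode == "partition":
        shuffled = rng.permutation(majority_idx)
        blocks = [shuffled[j * m_size : (j + 1) * m_size] for j in range(M)]
        leftover = shuffled[needed:]
    else:
        for _ in range(M):
            blocks.append(rng.choice(majority_idx, size=m_size, replace=False))
        leftover = np.setdiff1d(majority_idx, np.concatenate(blocks))

    subsets = []
    for block in blocks:
        rows = np.concatenate([block, minority_idx])
        subsets.append(train.subset(rng.permutation(rows)))
    return BalancedSubsets(
        subsets=subsets,
        M=M,
        minority_size=m_size,
        seed=seed,
        majority_blocks=blocks,
        minority_index=minority_idx,
        leftover=leftover,
        mode=mode,
    )
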
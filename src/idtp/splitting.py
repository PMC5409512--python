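"""Seeded stratified splits and folds (shared by the classifier and pipeline)."""

from __future__ import annotations

from typing import Sequence

import numpy as np


class SplitError(ValueError):
    pass


def stratified_split(
    labels: Sequence, train_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class random train/test partition, without replacement.

    Each class contributes round(train_fraction * class size) training
    rows (round half up).  The two index arrays are disjoint, exhaustive
    and returned sorted.  Deterministic given ``seed``.
    """
    if not 0.0 < train_fraction < 1.0:
        raise SplitError(f"train_fraction must be in (0, 1), got {train_fraction}")
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise SplitError("both classes must be present for a stratified split")
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 2:
            raise SplitError(f"class {cls!r} has fewer than 2 records")
        n_train = int(np.floor(train_fraction * len(idx) + 0.5))
        n_train = min(max(n_train, 1), len(idx) - 1)
        perm = rng.permutation(idx)
        train_parts.append(perm[:n_train])
        test_parts.append(perm[n_train:])
    train = np.sort(np.concatenate(train_parts))
    test = np.sort(np.concatenate(test_parts))
    return train, test


def stratified_kfold(labels: Sequence, n_folds: int, seed: int) -> list[np.ndarray]:
    """Class-proportion-preserving fold assignment; returns test-index arrays."""
    if n_folds < 2:
        raise SplitError("need at least 2 folds")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for cls in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == cls))
        for k, chunk in enumerate(np.array_split(idx, n_folds)):
            folds[k].extend(chunk.tolist())
    return [np.sort(np.asarray(f, dtype=int)) for f in folds]
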
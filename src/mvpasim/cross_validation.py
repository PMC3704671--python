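"""Cross-validation schemes for block-design decoding.

Two schemes whose contrast is the central estimation result:

* **Random time-point CV** — stratified 80/20 splits of individual
  volumes. Because HRF convolution makes temporally adjacent volumes
  similar, and adjacent volumes share a class in a block design, test
  volumes near training volumes leak information: performance on pure
  noise is inflated well above 50 %.

* **Leave-Block-Out CV (LBO-CV)** — one whole block per class is held
  out per fold, so the haemodynamic response cannot bridge training and
  test sets, and the mean performance estimate is unbiased. Each block
  serves as a test block once per *pairing*; with ``n_pairings = k``,
  each class-A block is tested k times, each time paired with a
  different class-B block (cyclic offset schedule), giving
  ``k * reps_per_class`` fold evaluations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from . import classification
from .sim_core import LabeledTimeseries, SeedLike, as_rng

__all__ = [
    "FoldResult",
    "PerformanceEstimate",
    "random_timepoint_cv",
    "leave_block_out_cv",
    "fold_success",
]


@dataclass(frozen=True)
class FoldResult:
    """Outcome of a single train/test evaluation.

    ``test_block_ids`` identifies the held-out blocks (one per class) for
    LBO-CV and is None for random time-point splits, where test sets are
    not aligned to blocks.
    """

    fold_index: int
    pairing_index: Optional[int]
    test_block_ids: Optional[Tuple[int, int]]
    n_test_points: int
    n_correct: int

    @property
    def accuracy_percent(self) -> float:
        return 100.0 * self.n_correct / self.n_test_points


@dataclass(frozen=True)
class PerformanceEstimate:
    """Per-fold accuracies plus their mean, in percent correct.

    ``n_trials`` (the number of fold evaluations) is the N a naive
    binomial significance test would use.
    """

    scheme: str  # 'random_cv' | 'lbo_cv'
    folds: Tuple[FoldResult, ...]

    @property
    def n_trials(self) -> int:
        return len(self.folds)

    @property
    def fold_accuracies(self) -> np.ndarray:
        return np.array([f.accuracy_percent for f in self.folds])

    @property
    def mean_percent(self) -> float:
        return float(self.fold_accuracies.mean())


def _fit(classifier: str, X: np.ndarray, y: np.ndarray, seed: SeedLike,
         standardize: bool = True):
    if classifier == "svm":
        return classification.fit_linear_svm(X, y, standardize=standardize)
    if classifier == "pearson":
        return classification.fit_pearson_classifier(X, y, seed=seed)
    raise ValueError(f"unknown classifier {classifier!r}")


def _evaluate(classifier: str, ts: LabeledTimeseries,
              train_idx: np.ndarray, test_idx: np.ndarray,
              seed: int, standardize: bool = True) -> tuple[int, int]:
    model = _fit(classifier, ts.data[train_idx], ts.labels[train_idx], seed,
                 standardize=standardize)
    pred = model.predict(ts.data[test_idx])
    n_correct = int(np.sum(pred == ts.labels[test_idx]))
    return n_correct, test_idx.size


def random_timepoint_cv(ts: LabeledTimeseries, train_frac: float = 0.8,
                        n_repeats: int = 100, seed: SeedLike = 0,
                        classifier: str = "svm",
                        standardize: bool = True) -> PerformanceEstimate:
    """Repeated stratified random splits of individual time points.

    Per repeat, ``floor(train_frac * n_c)`` volumes are drawn from each
    class ``c`` for training — the same count for both classes, so the
    training set is exactly class-balanced — and *all* remaining volumes
    form the test set. This is the leaky estimator: under temporal
    autocorrelation its mean on null data exceeds 50 %.
    """
    if ts.stage != "bold_trimmed":
        raise ValueError("random_timepoint_cv expects the bold_trimmed stage")
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    classes = np.unique(ts.labels)
    class_idx = [np.flatnonzero(ts.labels == c) for c in classes]
    n_train = min(int(np.floor(train_frac * idx.size)) for idx in class_idx)
    if n_train < 1 or any(idx.size - n_train < 1 for idx in class_idx):
        raise ValueError("too few time points per class for the split")
    rng = as_rng(seed)
    folds = []
    for r in range(n_repeats):
        train_parts = [rng.choice(idx, size=n_train, replace=False)
                       for idx in class_idx]
        train_idx = np.concatenate(train_parts)
        mask = np.ones(ts.n_timepoints, dtype=bool)
        mask[train_idx] = False
        test_idx = np.flatnonzero(mask)
        tie_seed = int(rng.integers(2 ** 31))
        n_correct, n_test = _evaluate(classifier, ts, train_idx, test_idx,
                                      tie_seed, standardize=standardize)
        folds.append(FoldResult(fold_index=r, pairing_index=None,
                                test_block_ids=None, n_test_points=n_test,
                                n_correct=n_correct))
    return PerformanceEstimate(scheme="random_cv", folds=tuple(folds))


def _block_groups(ts: LabeledTimeseries) -> tuple[np.ndarray, np.ndarray]:
    """Split blocks into the two per-class groups used for fold pairing.

    When labels are constant within blocks (the designed situation, and
    balanced block permutations of it), blocks are grouped by their class
    label in temporal order. When they are not — e.g. after a *global*
    label shuffle — class membership of a block is undefined, and folds
    fall back to the design's geometric pairing: consecutive blocks
    (0,1), (2,3), ... which coincides with label-based pairing on the
    unshuffled alternating design.
    """
    blocks = ts.block_list()
    if ts.labels_block_constant():
        block_label = np.array([ts.labels[ts.block_ids == b][0]
                                for b in blocks])
        classes = np.unique(block_label)
        if classes.size != 2:
            raise ValueError("need blocks of both classes")
        group_a = blocks[block_label == classes[0]]
        group_b = blocks[block_label == classes[1]]
    else:
        group_a = blocks[0::2]
        group_b = blocks[1::2]
    if group_a.size != group_b.size:
        raise ValueError("unequal number of blocks per class")
    return group_a, group_b


def leave_block_out_cv(ts: LabeledTimeseries, n_pairings: int = 1,
                       seed: SeedLike = 0, classifier: str = "svm",
                       standardize: bool = True) -> PerformanceEstimate:
    """Leave-Block-Out CV with optional repeated block pairings.

    Each fold holds out one block from each class (the test set) and
    trains on all remaining blocks. With ``n_pairings = 1`` the i-th A
    block is paired with the i-th B block (``reps_per_class`` folds).
    With ``n_pairings = k > 1``, pairing j shifts the B block by a cyclic
    offset, so every A block is tested k times with k different B
    partners; the order of the non-zero offsets is seeded.
    """
    if ts.stage != "bold_trimmed":
        raise ValueError("leave_block_out_cv expects the bold_trimmed stage")
    group_a, group_b = _block_groups(ts)
    reps = group_a.size
    if not 1 <= n_pairings <= reps:
        raise ValueError(
            f"n_pairings must be in [1, {reps}] for {reps} blocks per class")
    rng = as_rng(seed)
    offsets = [0]
    if n_pairings > 1:
        extra = rng.permutation(np.arange(1, reps))[: n_pairings - 1]
        offsets.extend(int(o) for o in extra)
    folds = []
    fold_index = 0
    for j, off in enumerate(offsets):
        for i in range(reps):
            a_block = int(group_a[i])
            b_block = int(group_b[(i + off) % reps])
            test_mask = (ts.block_ids == a_block) | (ts.block_ids == b_block)
            test_idx = np.flatnonzero(test_mask)
            train_idx = np.flatnonzero(~test_mask)
            tie_seed = int(rng.integers(2 ** 31))
            n_correct, n_test = _evaluate(classifier, ts, train_idx, test_idx,
                                          tie_seed, standardize=standardize)
            folds.append(FoldResult(fold_index=fold_index, pairing_index=j,
                                    test_block_ids=(a_block, b_block),
                                    n_test_points=n_test,
                                    n_correct=n_correct))
            fold_index += 1
    return PerformanceEstimate(scheme="lbo_cv", folds=tuple(folds))


def fold_success(fold: FoldResult, seed: SeedLike = 0) -> bool:
    """Binomial 'trial' outcome of a fold.

    Success means a strict majority of the fold's test points was
    classified correctly; an exact 50 % split is resolved by a seeded
    fair coin, which keeps the null success probability at 1/2.
    """
    if fold.n_test_points < 1:
        raise ValueError("fold has no test points")
    if 2 * fold.n_correct > fold.n_test_points:
        return True
    if 2 * fold.n_correct < fold.n_test_points:
        return False
    return bool(as_rng(seed).integers(0, 2))
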
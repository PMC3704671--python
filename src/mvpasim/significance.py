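"""Significance procedures for cross-validated classification performance.

Four tests, applied to a single subject's null-free question "is this
decoding performance above chance?":

* :func:`binomial_fold_test` — treats fold successes as independent coin
  flips. Invalid in practice: folds share training (and, with repeated
  pairings, test) data, so successes are positively correlated.
* :func:`t_test_vs_chance` — one-sample T-test of fold accuracies
  against 50 %. Invalid for the same dependence reason.
* :func:`global_permutation_null` — permutes labels freely over time
  points. Anticonservative: shuffling destroys the within-block label
  coherence that widens the true null performance distribution.
* :func:`block_permutation_null` — permutes class labels over whole
  blocks, balanced (equal block counts per class). This preserves the
  temporal correlation structure and is the valid test.

Permutation nulls are summarised by :func:`significance_from_null`,
which applies the strict 95th-percentile decision rule and also reports
an add-one permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Callable, Optional

import numpy as np
from scipy import stats

from .sim_core import LabeledTimeseries, SeedLike, as_rng, as_seed_sequence

__all__ = [
    "NullDistribution",
    "TestResult",
    "binomial_fold_test",
    "t_test_vs_chance",
    "global_permutation_null",
    "block_permutation_null",
    "random_balanced_assignment",
    "significance_from_null",
]

#: cv_procedure contract: (bold_trimmed timeseries, seed) -> object with
#: a ``mean_percent`` attribute (a PerformanceEstimate qualifies).
CVProcedure = Callable[[LabeledTimeseries, np.random.SeedSequence], object]


@dataclass(frozen=True)
class NullDistribution:
    """Permutation null: mean performances (percent) under shuffled labels."""

    values: np.ndarray
    scheme: str  # 'global' | 'block'
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size == 0:
            raise ValueError("null distribution must be a non-empty vector")
        if np.any((values < 0) | (values > 100)):
            raise ValueError("performance values must lie in [0, 100]")

    @property
    def n_perm(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class TestResult:
    """Decision and p-value of a significance procedure at level alpha."""

    method: str  # 'binomial' | 't_test' | 'perm_global' | 'perm_block'
    statistic: float
    p_value: Optional[float]
    reject: bool
    alpha: float = 0.05


def binomial_fold_test(n_success: int, n_trials: int,
                       alpha: float = 0.05) -> TestResult:
    """One-sided exact binomial tail test of fold successes vs p = 1/2.

    ``p = P(X >= n_success)`` for X ~ Binomial(n_trials, 0.5); reject
    when p <= alpha. Valid only if fold outcomes were independent —
    which, for cross-validated folds, they are not.
    """
    if n_trials < 1 or not 0 <= n_success <= n_trials:
        raise ValueError("need 0 <= n_success <= n_trials and n_trials >= 1")
    p = float(stats.binomtest(n_success, n_trials, p=0.5,
                              alternative="greater").pvalue)
    return TestResult(method="binomial", statistic=float(n_success),
                      p_value=p, reject=p <= alpha, alpha=alpha)


def t_test_vs_chance(fold_accuracies, mu: float = 50.0,
                     alpha: float = 0.05) -> TestResult:
    """Two-sided one-sample T-test of fold accuracies against chance.

    Degenerate zero-variance inputs are resolved by convention: p = 1
    when the common value equals ``mu`` (nothing to detect), p = 0 when
    it does not (an exact, if pathological, displacement).
    """
    acc = np.asarray(fold_accuracies, dtype=float)
    if acc.size < 2:
        raise ValueError("need at least 2 fold accuracies")
    if np.ptp(acc) == 0:
        if acc[0] == mu:
            return TestResult(method="t_test", statistic=0.0, p_value=1.0,
                              reject=False, alpha=alpha)
        return TestResult(method="t_test",
                          statistic=float(np.sign(acc[0] - mu)) * np.inf,
                          p_value=0.0, reject=True, alpha=alpha)
    t, p = stats.ttest_1samp(acc, mu)
    return TestResult(method="t_test", statistic=float(t), p_value=float(p),
                      reject=bool(p <= alpha), alpha=alpha)


def _spawned_cv_seeds(seed: SeedLike, n: int):
    ss = as_seed_sequence(seed)
    children = ss.spawn(n + 1)
    return as_rng(children[0]), children[1:]


def global_permutation_null(ts: LabeledTimeseries, cv_procedure: CVProcedure,
                            n_perm: int = 1000,
                            seed: SeedLike = 0) -> NullDistribution:
    """Null distribution from unrestricted label shuffles.

    Each permutation rearranges the per-time-point labels uniformly over
    the whole dataset (class counts are automatically preserved) and
    re-runs the identical CV procedure on the permuted labels.
    """
    if ts.stage != "bold_trimmed":
        raise ValueError("permutation tests expect the bold_trimmed stage")
    if n_perm < 20:
        raise ValueError("n_perm < 20 makes the percentile rule meaningless")
    rng, cv_seeds = _spawned_cv_seeds(seed, n_perm)
    values = np.empty(n_perm)
    for k in range(n_perm):
        shuffled = rng.permutation(ts.labels)
        est = cv_procedure(ts.with_labels(shuffled), cv_seeds[k])
        values[k] = est.mean_percent
    return NullDistribution(values=values, scheme="global",
                            seed=_seed_repr(seed))


def random_balanced_assignment(n_blocks: int,
                               rng: np.random.Generator) -> np.ndarray:
    """Uniformly random balanced split of blocks into two classes.

    Returns a boolean mask of length ``n_blocks`` with exactly half True
    (class A). All C(n_blocks, n_blocks/2) assignments are equally
    likely.
    """
    if n_blocks % 2:
        raise ValueError("balanced assignment needs an even block count")
    mask = np.zeros(n_blocks, dtype=bool)
    mask[rng.permutation(n_blocks)[: n_blocks // 2]] = True
    return mask


def block_permutation_null(ts: LabeledTimeseries, cv_procedure: CVProcedure,
                           n_perm: int = 1000,
                           seed: SeedLike = 0) -> NullDistribution:
    """Null distribution from balanced whole-block label permutations.

    Every permutation reassigns class labels to entire blocks, with
    exactly half the blocks per class, keeping within-block temporal
    label structure intact; the identical CV procedure is then re-run.
    Assignments are sampled with replacement from the balanced space.
    """
    if ts.stage != "bold_trimmed":
        raise ValueError("permutation tests expect the bold_trimmed stage")
    if n_perm < 20:
        raise ValueError("n_perm < 20 makes the percentile rule meaningless")
    blocks = ts.block_list()
    if blocks.size % 2:
        raise ValueError("block permutation needs an even number of blocks")
    classes = np.unique(ts.labels)
    if classes.size != 2:
        raise ValueError("need exactly two classes")
    block_index = np.searchsorted(blocks, ts.block_ids)
    rng, cv_seeds = _spawned_cv_seeds(seed, n_perm)
    values = np.empty(n_perm)
    for k in range(n_perm):
        is_a = random_balanced_assignment(blocks.size, rng)
        per_block = np.where(is_a, classes[0], classes[1])
        est = cv_procedure(ts.with_labels(per_block[block_index]),
                           cv_seeds[k])
        values[k] = est.mean_percent
    return NullDistribution(values=values, scheme="block",
                            seed=_seed_repr(seed))


def significance_from_null(observed_percent: float, null: NullDistribution,
                           alpha: float = 0.05) -> TestResult:
    """Percentile decision rule plus an add-one permutation p-value.

    Reject when the observed performance *strictly* exceeds the
    empirical 95th percentile of the null — the order statistic at
    1-based index ``ceil(0.95 * n_perm)``, no interpolation. The
    reported p-value is ``(1 + #{null >= observed}) / (n_perm + 1)``,
    which is never anticonservative.
    """
    ordered = np.sort(null.values)
    cutoff = ordered[ceil((1 - alpha) * null.n_perm) - 1]
    p = (1 + int(np.sum(null.values >= observed_percent))) / (null.n_perm + 1)
    return TestResult(method=f"perm_{null.scheme}",
                      statistic=float(observed_percent), p_value=float(p),
                      reject=bool(observed_percent > cutoff), alpha=alpha)


def _seed_repr(seed: SeedLike) -> Optional[int]:
    return seed if isinstance(seed, (int, np.integer)) else None
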
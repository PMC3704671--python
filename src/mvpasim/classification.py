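"""Classifiers and performance scoring.

Two classifier families: a linear support vector machine (the workhorse
of MVPA decoding) and a Pearson-correlation template matcher. Both are
exposed through a tiny uniform interface — ``fit_*`` returns a
:class:`TrainedClassifier` whose ``predict`` maps a time-points x voxels
matrix to class labels — so cross-validation code is classifier-agnostic.

Voxels are standardised with the *training* fold's mean and standard
deviation only (applied unchanged to test data), avoiding an extra
leakage channel; this can be switched off via ``standardize=False``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from sklearn.svm import SVC

from .sim_core import SeedLike, as_rng

__all__ = [
    "TrainedClassifier",
    "fit_linear_svm",
    "fit_pearson_classifier",
    "score_accuracy",
]


@dataclass
class TrainedClassifier:
    """A fitted classifier: ``kind``, the two class labels, and a predictor."""

    kind: str
    class_labels: tuple
    n_features: int
    _predict: Callable[[np.ndarray], np.ndarray]

    def predict(self, data: np.ndarray) -> np.ndarray:
        data = np.atleast_2d(np.asarray(data, dtype=float))
        if data.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} voxels, got {data.shape[1]}")
        return self._predict(data)


def _check_training(train_data: np.ndarray, train_labels: np.ndarray):
    X = np.asarray(train_data, dtype=float)
    y = np.asarray(train_labels)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("train_data must be 2-D with one label per row")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(
            f"training set must contain exactly two classes, got {classes!r}")
    return X, y, classes


def fit_linear_svm(train_data: np.ndarray, train_labels: np.ndarray,
                   C: float = 1.0,
                   standardize: bool = True) -> TrainedClassifier:
    """Fit a linear soft-margin SVM (C=1 by default).

    Deterministic for fixed input. Standardisation statistics come from
    the training data only; constant voxels are left unscaled.
    """
    X, y, classes = _check_training(train_data, train_labels)
    if standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
    else:
        mu = np.zeros(X.shape[1])
        sd = np.ones(X.shape[1])
    model = SVC(kernel="linear", C=C)
    model.fit((X - mu) / sd, y)

    def predict(data: np.ndarray) -> np.ndarray:
        return model.predict((data - mu) / sd)

    return TrainedClassifier(kind="linear_svm",
                             class_labels=tuple(classes),
                             n_features=X.shape[1], _predict=predict)


def _zscore_rows(X: np.ndarray) -> np.ndarray:
    # Rows with zero variance map to the zero vector, which yields a
    # Pearson correlation of 0 against anything (the documented default
    # for degenerate patterns).
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    safe = np.where(sd > 0, sd, 1.0)
    z = (X - mu) / safe
    z[np.ravel(sd == 0)] = 0.0
    return z


def fit_pearson_classifier(train_data: np.ndarray, train_labels: np.ndarray,
                           seed: SeedLike = 0) -> TrainedClassifier:
    """Fit a correlation template classifier.

    A test pattern is assigned to the class whose training patterns have
    the higher *mean* Pearson correlation with it. Zero-variance patterns
    (test or training) contribute a correlation of 0. Exact ties between
    the two class scores are broken by a seeded fair coin.
    """
    X, y, classes = _check_training(train_data, train_labels)
    if X.shape[1] < 2:
        raise ValueError("Pearson classification needs >= 2 voxels")
    z_train = _zscore_rows(X)
    masks = [y == c for c in classes]
    rng = as_rng(seed)

    def predict(data: np.ndarray) -> np.ndarray:
        z_test = _zscore_rows(np.asarray(data, dtype=float))
        # r[i, j] = Pearson correlation of test i with training pattern j
        r = z_test @ z_train.T / X.shape[1]
        scores = np.column_stack([r[:, m].mean(axis=1) for m in masks])
        winner = np.argmax(scores, axis=1)
        ties = scores[:, 0] == scores[:, 1]
        if np.any(ties):
            winner[ties] = rng.integers(0, 2, size=int(ties.sum()))
        return classes[winner]

    return TrainedClassifier(kind="pearson", class_labels=tuple(classes),
                             n_features=X.shape[1], _predict=predict)


def score_accuracy(predictions, truth) -> float:
    """Percent of items classified correctly, in [0, 100]."""
    pred = np.asarray(predictions)
    true = np.asarray(truth)
    if pred.shape != true.shape:
        raise ValueError("predictions and truth must have equal length")
    if pred.size == 0:
        raise ValueError("cannot score an empty prediction set")
    return 100.0 * float(np.mean(pred == true))
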
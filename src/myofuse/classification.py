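"""Linear discriminant analysis and leave-one-repetition-out cross-validation.

The classifier is the Gaussian shared-covariance LDA: class k scores

    delta_k(x) = x' S^-1 mu_k - 1/2 mu_k' S^-1 mu_k + ln pi_k

with per-class sample means mu_k, pooled within-class covariance
S = sum_k sum_{i in k} (x - mu_k)(x - mu_k)' / (n - K), and empirical
priors pi_k.  A small shrinkage toward the scaled identity,
S_hat = (1 - lam) S + lam tr(S)/D I, guarantees invertibility when folds
are small relative to the feature dimension.  Ties break to the earliest
class in the model's label order.

Cross-validation folds are the trial repetitions: fold r trains on every
window whose repetition differs from r and tests on repetition r, and the
window-level predictions of all folds accumulate into one confusion
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Sequence

import numpy as np
from scipy import linalg

__all__ = [
    "DEFAULT_SHRINKAGE",
    "LDAModel",
    "ConfusionMatrix",
    "fit_lda",
    "predict",
    "discriminant_scores",
    "accuracy",
    "leave_one_repetition_out_cv",
]

DEFAULT_SHRINKAGE = 1e-3


def _label_array(y) -> np.ndarray:
    """1-D object array of labels (tuples stay scalar elements)."""
    arr = np.empty(len(y), dtype=object)
    arr[:] = list(y)
    return arr


def _encode(y: np.ndarray, labels: list) -> np.ndarray:
    index = {lab: i for i, lab in enumerate(labels)}
    return np.fromiter((index[v] for v in y), dtype=np.intp, count=len(y))


@dataclass
class LDAModel:
    class_labels: list
    class_means: np.ndarray  # (K, D)
    pooled_covariance: np.ndarray  # (D, D), after shrinkage
    precision: np.ndarray  # (D, D), inverse of the shrunk covariance
    class_priors: np.ndarray  # (K,)
    shrinkage: float

    @property
    def n_features(self) -> int:
        return self.class_means.shape[1]


@dataclass
class ConfusionMatrix:
    """Square count matrix; rows are true classes, columns predictions."""

    labels: list
    counts: np.ndarray  # (K, K) non-negative integers

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square and match the label list")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    def row_normalized_pct(self) -> np.ndarray:
        """Rows rescaled to percentages (each row sums to 100)."""
        row_sums = self.counts.sum(axis=1, keepdims=True)
        if np.any(row_sums == 0):
            empty = [self.labels[i] for i in np.where(row_sums[:, 0] == 0)[0]]
            raise ValueError(f"empty confusion-matrix rows for classes {empty}")
        return 100.0 * self.counts / row_sums


def accuracy(confusion: ConfusionMatrix) -> float:
    """Diagonal mean of the row-normalised matrix (macro per-class recall, %)."""
    return float(np.mean(np.diag(confusion.row_normalized_pct())))


def fit_lda(
    X: np.ndarray,
    y: Sequence[Hashable],
    class_order: Sequence[Hashable] | None = None,
    shrinkage: float = DEFAULT_SHRINKAGE,
) -> LDAModel:
    """Fit shared-covariance LDA with shrinkage regularisation.

    ``class_order`` fixes the label ordering (and hence tie-breaking);
    by default labels appear in sorted order.  Every class needs at least
    two samples so the pooled covariance is well defined.
    """
    X = np.asarray(X, dtype=float)
    y = _label_array(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n_samples, n_features) aligned with y")
    if not 0 <= shrinkage <= 1:
        raise ValueError("shrinkage must lie in [0, 1]")

    present = set(y)
    if class_order is None:
        labels = sorted(present)
    else:
        labels = [c for c in class_order if c in present]
        if present - set(labels):
            raise ValueError(f"labels {present - set(labels)} missing from class_order")
    if len(labels) < 2:
        raise ValueError("LDA needs at least 2 classes")

    codes = _encode(y, labels)
    n, d = X.shape
    k = len(labels)
    means = np.empty((k, d))
    priors = np.empty(k)
    scatter = np.zeros((d, d))
    for i, lab in enumerate(labels):
        Xi = X[codes == i]
        if Xi.shape[0] < 2:
            raise ValueError(f"class {lab!r} has fewer than 2 samples")
        means[i] = Xi.mean(axis=0)
        priors[i] = Xi.shape[0] / n
        centred = Xi - means[i]
        scatter += centred.T @ centred
    pooled = scatter / (n - k)

    if shrinkage > 0:
        target = np.trace(pooled) / d
        pooled = (1.0 - shrinkage) * pooled + shrinkage * target * np.eye(d)
    precision = linalg.inv(pooled, check_finite=False)
    precision = (precision + precision.T) / 2.0  # keep exactly symmetric

    return LDAModel(
        class_labels=list(labels),
        class_means=means,
        pooled_covariance=pooled,
        precision=precision,
        class_priors=priors,
        shrinkage=shrinkage,
    )


def discriminant_scores(model: LDAModel, X: np.ndarray) -> np.ndarray:
    """Linear discriminant scores delta_k(x) for each sample and class."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model "
            f"({model.n_features})"
        )
    W = model.precision @ model.class_means.T  # (D, K)
    bias = -0.5 * np.einsum("kd,dk->k", model.class_means, W) + np.log(
        model.class_priors
    )
    return X @ W + bias[None, :]


def predict(model: LDAModel, X: np.ndarray) -> np.ndarray:
    """Most probable class per sample; ties go to the earliest label."""
    scores = discriminant_scores(model, X)
    idx = np.argmax(scores, axis=1)  # argmax takes the first maximum
    return np.asarray(model.class_labels, dtype=object)[idx]


def leave_one_repetition_out_cv(
    X: np.ndarray,
    y: Sequence[Hashable],
    repetitions: Sequence[int],
    class_order: Sequence[Hashable] | None = None,
    shrinkage: float = DEFAULT_SHRINKAGE,
) -> ConfusionMatrix:
    """Leave-one-repetition-out CV accumulating one window-level matrix.

    For each distinct repetition r the classifier trains on all windows
    with repetition != r and is tested on repetition r; every window is
    therefore tested exactly once.  Every class must appear in every
    training fold.
    """
    X = np.asarray(X, dtype=float)
    y = _label_array(y)
    reps = np.asarray(repetitions)
    if not (X.shape[0] == y.shape[0] == reps.shape[0]):
        raise ValueError("X, y and repetitions must be aligned")

    present = set(y)
    if class_order is None:
        labels = sorted(present)
    else:
        labels = [c for c in class_order if c in present]
    codes = _encode(y, labels)
    k = len(labels)
    counts = np.zeros((k, k), dtype=int)

    for r in np.unique(reps):
        train = reps != r
        test = ~train
        missing = present - set(y[train])
        if missing:
            raise ValueError(
                f"classes {sorted(map(str, missing))} absent from the training "
                f"fold holding out repetition {r}"
            )
        model = fit_lda(X[train], y[train], class_order=labels, shrinkage=shrinkage)
        pred_codes = np.argmax(discriminant_scores(model, X[test]), axis=1)
        np.add.at(counts, (codes[test], pred_codes), 1)

    return ConfusionMatrix(labels=labels, counts=counts)
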
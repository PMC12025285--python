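"""Multi-kernel SVM fusion of modality-specific representations.

After feature selection, each modality's selected features are concatenated
across time points into one vector per subject, a linear Gram matrix is
computed per modality, and the modality kernels are fused as a convex
combination ``K = sum_m beta_m K_m`` with ``beta_m >= 0, sum beta_m = 1``.
The mixing weights are chosen by grid search over the simplex, scored by
stratified tenfold cross-validation accuracy on the training set only, and
the final classifier is an SVM on the precomputed mixed kernel (all SVM
cost parameters at library defaults, C = 1, unless overridden).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .solver import CohortTable, FeatureSelection

__all__ = [
    "KernelSet",
    "modality_vectors",
    "linear_gram",
    "combine",
    "simplex_grid",
    "tune_and_train",
    "predict",
    "TrainedClassifier",
]


@dataclass(frozen=True)
class KernelSet:
    """Per-modality Gram matrices, simplex mixing weights, and their fusion."""

    grams: tuple[np.ndarray, ...]
    mix_weights: np.ndarray
    mixed: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.mix_weights, dtype=float)
        if (w < -1e-12).any() or abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("mix_weights must lie on the probability simplex")


@dataclass
class TrainedClassifier:
    """A fitted precomputed-kernel SVM plus what is needed to score new data."""

    svm: SVC
    mix_weights: np.ndarray
    n_train: int
    cv_accuracy: float


def modality_vectors(
    data: CohortTable, selection: FeatureSelection
) -> list[np.ndarray]:
    """Concatenate each modality's selected features across time points.

    For modality ``m`` with selected feature set ``S_m`` the output block is
    ``[X_m1[:, S_m] | ... | X_mT[:, S_m]]`` — subjects stay in cohort order,
    columns are grouped by time point.  Modalities with an empty selection
    yield a zero-width block; raising only when every modality is empty.
    """
    sel = selection.per_modality
    if all(len(s) == 0 for s in sel):
        raise ValueError("no features selected")
    out = []
    for m in range(data.n_modalities):
        cols = list(sel[m]) if m < len(sel) else []
        blocks = [data.cell(m, t)[:, cols] for t in range(data.n_timepoints)]
        out.append(np.concatenate(blocks, axis=1) if blocks else np.empty((data.n_subjects, 0)))
    return out


def linear_gram(A: np.ndarray, B: np.ndarray | None = None) -> np.ndarray:
    """Linear kernel matrix of row inner products.

    ``linear_gram(A)`` is the symmetric train-train Gram ``A A^T``;
    ``linear_gram(A, B)`` gives the cross Gram ``B A^T`` (rows of ``B``
    against rows of ``A``), the layout scikit-learn expects for scoring a
    precomputed-kernel SVM on new data.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    if B is None:
        K = A @ A.T
        return 0.5 * (K + K.T)
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("feature dimension mismatch between A and B")
    return B @ A.T


def combine(grams: list[np.ndarray], mix_weights: np.ndarray) -> np.ndarray:
    """Convex combination ``sum_m beta_m K_m`` of per-modality kernels."""
    w = np.asarray(mix_weights, dtype=float)
    if len(grams) != w.size:
        raise ValueError("one weight per Gram matrix required")
    if (w < -1e-9).any() or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("mix_weights must lie on the probability simplex")
    out = np.zeros_like(grams[0], dtype=float)
    for K, b in zip(grams, w):
        out += b * K
    return out


def simplex_grid(n_modalities: int, step: float) -> list[np.ndarray]:
    """All simplex points with coordinates that are multiples of ``step``.

    For M=2 and step 0.1 this is the 11 candidates (1, 0), (0.9, 0.1), ...,
    (0, 1).  Ordering is deterministic (first coordinate descending), so
    grid-search ties break toward the first candidate.
    """
    n_steps = int(round(1.0 / step))
    pts = []
    for combo in product(range(n_steps, -1, -1), repeat=n_modalities - 1):
        rest = n_steps - sum(combo)
        if rest >= 0:
            pts.append(np.array(combo + (rest,), dtype=float) / n_steps)
    return pts


def tune_and_train(
    vectors: list[np.ndarray],
    labels: np.ndarray,
    weight_grid_step: float = 0.1,
    C: float = 1.0,
    n_folds: int = 10,
    seed: int = 0,
) -> TrainedClassifier:
    """Grid-search the kernel mixing weights and fit the final SVM.

    Each simplex candidate is scored by stratified ``n_folds``-fold CV
    accuracy on the training set (folds derived from ``seed`` so nested CV
    is reproducible); the winner — first candidate on ties — is refit on the
    full training Gram.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2 or counts.min() < 2:
        raise ValueError("need at least 2 training subjects per class")
    grams = [linear_gram(V) for V in vectors]
    n = y.size
    n_folds_eff = min(n_folds, int(counts.min()))
    skf = StratifiedKFold(n_splits=n_folds_eff, shuffle=True, random_state=seed)
    folds = list(skf.split(np.zeros(n), y))

    best_w, best_acc = None, -1.0
    for w in simplex_grid(len(vectors), weight_grid_step):
        K = combine(grams, w)
        correct = 0
        for tr, te in folds:
            clf = SVC(kernel="precomputed", C=C)
            clf.fit(K[np.ix_(tr, tr)], y[tr])
            correct += int((clf.predict(K[np.ix_(te, tr)]) == y[te]).sum())
        acc = correct / n
        if acc > best_acc:  # strict: ties keep the earlier candidate
            best_acc, best_w = acc, w

    clf = SVC(kernel="precomputed", C=C)
    clf.fit(combine(grams, best_w), y)
    return TrainedClassifier(clf, best_w, n, best_acc)


def predict(
    classifier: TrainedClassifier, mixed_gram: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels and decision scores from a test-vs-train mixed Gram.

    ``mixed_gram`` must be n_test x n_train, computed with the classifier's
    own mix weights and training subject order.
    """
    K = np.atleast_2d(np.asarray(mixed_gram, dtype=float))
    if K.shape[1] != classifier.n_train:
        raise ValueError("Gram column count does not match training subjects")
    labels = classifier.svm.predict(K)
    scores = classifier.svm.decision_function(K)
    return labels.astype(int), scores
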
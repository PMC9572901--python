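"""Leave-one-out cross-validated error of a gene subset under k-NN or SVM.

LOOCV here is the standard orientation: for each of the n samples, the
classifier is trained on the other n-1 and predicts the held-out one; the
error rate is the misclassified fraction. Per-gene min-max scaling (when
enabled) is fit on each training fold only, so no information about the
held-out sample leaks into its own fold.

k-NN is implemented directly so that its tie-breaking is a fixed contract:
distance ties resolve toward the lower training-sample index, and vote ties
resolve toward the class listed earlier in ``class_names``. The SVM is
scikit-learn's soft-margin SVC (one-vs-one for multiclass).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import sklearn
from sklearn.svm import SVC

from .data import ExpressionDataset

__all__ = ["FitnessSpec", "loocv_error", "knn_predict", "svm_fit_predict"]


@dataclass
class FitnessSpec:
    """Classifier choice and hyperparameters for the LOOCV fitness.

    ``k_neighbors`` defaults to 7, the value reported to work well across
    the classic microarray benchmarks; it must be a positive odd integer so
    binary votes cannot tie. SVM defaults are a linear kernel with C = 1.
    """

    classifier: str = "knn"
    k_neighbors: int = 7
    svm_kernel: str = "linear"
    svm_c: float = 1.0
    scaling: str = "minmax"

    def __post_init__(self) -> None:
        if self.classifier not in ("knn", "svm"):
            raise ValueError(f"classifier must be 'knn' or 'svm', got {self.classifier!r}")
        if self.classifier == "knn":
            if self.k_neighbors < 1 or self.k_neighbors % 2 == 0:
                raise ValueError(
                    f"k_neighbors must be a positive odd integer, got {self.k_neighbors}"
                )
        if self.svm_kernel not in ("linear", "rbf"):
            raise ValueError(f"svm_kernel must be 'linear' or 'rbf', got {self.svm_kernel!r}")
        if self.svm_c <= 0:
            raise ValueError("svm_c must be positive")
        if self.scaling not in ("minmax", "none"):
            raise ValueError(f"scaling must be 'minmax' or 'none', got {self.scaling!r}")


def _minmax_fit(train: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lo = train.min(axis=0)
    span = train.max(axis=0) - lo
    span[span == 0.0] = 1.0  # constant gene maps to 0 everywhere
    return lo, span


def _scale(x: np.ndarray, lo: np.ndarray, span: np.ndarray) -> np.ndarray:
    return (x - lo) / span


def knn_predict(
    train_matrix: np.ndarray,
    train_labels: np.ndarray,
    test_vector: np.ndarray,
    k_neighbors: int,
    scaling: str = "minmax",
    n_classes: int | None = None,
) -> int:
    """Majority label among the k Euclidean-nearest training samples.

    ``train_labels`` are integer class codes (position in class_names).
    Distance ties break toward the lower training index (stable argsort);
    vote ties break toward the smaller class code.
    """
    train_matrix = np.asarray(train_matrix, dtype=float)
    train_labels = np.asarray(train_labels)
    if k_neighbors > train_matrix.shape[0]:
        raise ValueError(
            f"k_neighbors={k_neighbors} exceeds {train_matrix.shape[0]} training samples"
        )
    if scaling == "minmax":
        lo, span = _minmax_fit(train_matrix)
        train_matrix = _scale(train_matrix, lo, span)
        test_vector = _scale(np.asarray(test_vector, dtype=float), lo, span)
    d2 = ((train_matrix - test_vector) ** 2).sum(axis=1)
    order = np.argsort(d2, kind="stable")[:k_neighbors]
    if n_classes is None:
        n_classes = int(train_labels.max()) + 1
    votes = np.bincount(train_labels[order], minlength=n_classes)
    return int(np.argmax(votes))  # argmax takes the earliest class on ties


def svm_fit_predict(
    train_matrix: np.ndarray,
    train_labels: np.ndarray,
    test_vector: np.ndarray,
    spec: FitnessSpec,
) -> int:
    """Soft-margin SVM prediction for one held-out sample.

    A training fold containing a single class cannot be fit; the rule for
    that degenerate fold is to predict that class.
    """
    train_labels = np.asarray(train_labels)
    classes = np.unique(train_labels)
    if classes.size == 1:
        return int(classes[0])
    train_matrix = np.asarray(train_matrix, dtype=float)
    test_vector = np.asarray(test_vector, dtype=float)
    if spec.scaling == "minmax":
        lo, span = _minmax_fit(train_matrix)
        train_matrix = _scale(train_matrix, lo, span)
        test_vector = _scale(test_vector, lo, span)
    with sklearn.config_context(assume_finite=True):
        model = SVC(kernel=spec.svm_kernel, C=spec.svm_c)
        model.fit(train_matrix, train_labels)
        return int(model.predict(test_vector[np.newaxis, :])[0])


def loocv_error(
    dataset: ExpressionDataset,
    gene_indices,
    spec: FitnessSpec,
) -> float:
    """LOOCV error rate of the classifier restricted to ``gene_indices``.

    Deterministic given (dataset, subset, spec); the result is always a
    multiple of 1/n_samples.
    """
    gene_indices = np.asarray(list(gene_indices), dtype=np.intp)
    if gene_indices.size == 0:
        raise ValueError("gene subset is empty")
    if gene_indices.min() < 0 or gene_indices.max() >= dataset.n_genes:
        raise ValueError(
            f"gene indices out of range [0, {dataset.n_genes})"
        )
    n = dataset.n_samples
    if spec.classifier == "knn" and spec.k_neighbors >= n:
        raise ValueError(
            f"k_neighbors={spec.k_neighbors} must be < n_samples={n} for LOOCV"
        )
    X = dataset.matrix[:, gene_indices]
    y = dataset.label_codes()
    n_classes = dataset.n_classes

    errors = 0
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        X_tr, y_tr = X[mask], y[mask]
        if spec.classifier == "knn":
            pred = knn_predict(
                X_tr, y_tr, X[i], spec.k_neighbors, spec.scaling, n_classes
            )
        else:
            pred = svm_fit_predict(X_tr, y_tr, X[i], spec)
        if pred != y[i]:
            errors += 1
        mask[i] = True
    return errors / n
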
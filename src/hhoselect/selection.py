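"""Decode continuous hawk positions into fixed-size gene subsets and run
the complete wrapper selector (HHO-KNN / HHO-SVM).

The optimizer searches the continuous box [0, 1]^n_genes; a position is
decoded to a subset by taking the indices of its ``n_selected`` largest
coordinates (ties toward the lower index). The subset size is therefore an
exact, externally controlled quantity, and the fitness minimized is the
subset's LOOCV error rate alone — no size penalty is needed.

``HHOGeneSelector`` packages the whole thing as a scikit-learn feature
selector: ``fit(X, y)`` runs the search, ``transform(X)`` keeps the
selected gene columns, and it composes with sklearn pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .data import ExpressionDataset
from .fitness import FitnessSpec, loocv_error
from .hho import HHOParams, HHOResult, hho_minimize

__all__ = [
    "SubsetSolution",
    "decode_position",
    "make_subset_fitness",
    "select_genes",
    "HHOGeneSelector",
]


@dataclass
class SubsetSolution:
    """A decoded gene subset with its LOOCV performance."""

    gene_indices: np.ndarray  # sorted, unique, size n_selected
    position: np.ndarray
    error_rate: float
    accuracy: float
    history: np.ndarray = field(default=None, repr=False)
    n_evaluations: int = 0

    @property
    def n_selected(self) -> int:
        return self.gene_indices.size


def decode_position(position: np.ndarray, n_selected: int) -> np.ndarray:
    """Indices of the ``n_selected`` largest coordinates, sorted ascending.

    Ties break toward the lower index; any strictly monotone transform of
    the position decodes to the identical subset (rank equivariance).
    """
    position = np.asarray(position, dtype=float)
    n_genes = position.size
    if not 1 <= n_selected <= n_genes:
        raise ValueError(
            f"n_selected={n_selected} must be in [1, {n_genes}] (number of genes)"
        )
    order = np.argsort(-position, kind="stable")  # stable: ties -> lower index
    return np.sort(order[:n_selected])


def make_subset_fitness(
    dataset: ExpressionDataset,
    n_selected: int,
    spec: FitnessSpec,
    memoize: bool = True,
):
    """Objective over positions: LOOCV error of the decoded subset.

    Many positions decode to the same subset, so results are memoized by
    the (frozen) index tuple; caching is purely an efficiency measure and
    never changes results.
    """
    cache: dict[tuple, float] = {}

    def objective(position: np.ndarray) -> float:
        idx = decode_position(position, n_selected)
        key = tuple(idx.tolist())
        if memoize and key in cache:
            return cache[key]
        err = loocv_error(dataset, idx, spec)
        if memoize:
            cache[key] = err
        return err

    objective.cache = cache
    return objective


def select_genes(
    dataset: ExpressionDataset,
    n_selected: int,
    fitness_spec: FitnessSpec | None = None,
    params: HHOParams | None = None,
    seed: int | None = None,
) -> SubsetSolution:
    """Run one wrapper-selection search and return the decoded rabbit.

    Thin functional wrapper over the same machinery as
    :class:`HHOGeneSelector`; ``params.dim`` is forced to ``n_genes``.
    """
    if fitness_spec is None:
        fitness_spec = FitnessSpec()
    if n_selected > dataset.n_genes:
        raise ValueError(
            f"n_selected={n_selected} exceeds n_genes={dataset.n_genes}"
        )
    if params is None:
        params = HHOParams(dim=dataset.n_genes, seed=seed)
    elif params.dim != dataset.n_genes:
        params = HHOParams(
            dim=dataset.n_genes,
            n_hawks=params.n_hawks,
            max_iter=params.max_iter,
            lb=params.lb,
            ub=params.ub,
            seed=params.seed if seed is None else seed,
        )
    objective = make_subset_fitness(dataset, n_selected, fitness_spec)
    result: HHOResult = hho_minimize(objective, params)
    idx = decode_position(result.best_position, n_selected)
    err = float(result.best_fitness)
    return SubsetSolution(
        gene_indices=idx,
        position=result.best_position,
        error_rate=err,
        accuracy=1.0 - err,
        history=result.history,
        n_evaluations=result.n_evaluations,
    )


class HHOGeneSelector(SelectorMixin, BaseEstimator):
    """Wrapper gene selection by Harris Hawks Optimization.

    The selector searches for the ``n_genes_to_select`` genes whose
    leave-one-out cross-validated error under the chosen classifier is
    minimal, using HHO over continuous gene scores decoded by top-k rank.

    Parameters
    ----------
    n_genes_to_select : int, default=10
        Exact size of the selected gene subset.
    classifier : {'knn', 'svm'}, default='knn'
        Classifier whose LOOCV error is the search fitness.
    n_neighbors : int, default=7
        k for the k-NN classifier (positive odd).
    svm_kernel : {'linear', 'rbf'}, default='linear'
    svm_C : float, default=1.0
    scaling : {'minmax', 'none'}, default='minmax'
        Per-gene scaling fit inside each training fold.
    n_hawks : int, default=10
    max_iter : int, default=100
        Population size and iteration budget of the optimizer.
    random_state : int or None, default=None

    Attributes
    ----------
    support_ : bool ndarray of shape (n_features,)
        Mask of selected genes.
    selected_indices_ : int ndarray of shape (n_genes_to_select,)
        Sorted selected column indices.
    error_rate_, accuracy_ : float
        LOOCV error/accuracy of the selected subset.
    history_ : ndarray of shape (max_iter,)
        Best fitness per optimizer iteration (non-increasing).

    Examples
    --------
    >>> sel = HHOGeneSelector(n_genes_to_select=2, max_iter=20, random_state=0)
    >>> Xt = sel.fit_transform(X, y)   # doctest: +SKIP
    """

    def __init__(
        self,
        n_genes_to_select: int = 10,
        classifier: str = "knn",
        n_neighbors: int = 7,
        svm_kernel: str = "linear",
        svm_C: float = 1.0,
        scaling: str = "minmax",
        n_hawks: int = 10,
        max_iter: int = 100,
        random_state: int | None = None,
    ):
        self.n_genes_to_select = n_genes_to_select
        self.classifier = classifier
        self.n_neighbors = n_neighbors
        self.svm_kernel = svm_kernel
        self.svm_C = svm_C
        self.scaling = scaling
        self.n_hawks = n_hawks
        self.max_iter = max_iter
        self.random_state = random_state

    def _fitness_spec(self) -> FitnessSpec:
        return FitnessSpec(
            classifier=self.classifier,
            k_neighbors=self.n_neighbors,
            svm_kernel=self.svm_kernel,
            svm_c=self.svm_C,
            scaling=self.scaling,
        )

    def fit(self, X, y):
        X, y = validate_data(self, X, y, ensure_min_samples=2)
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("y must contain at least 2 classes")
        dataset = ExpressionDataset(
            matrix=X,
            gene_ids=[f"g{j}" for j in range(X.shape[1])],
            labels=y.astype(str),
            class_names=[str(c) for c in classes],
        )
        solution = select_genes(
            dataset,
            self.n_genes_to_select,
            fitness_spec=self._fitness_spec(),
            params=HHOParams(
                dim=X.shape[1],
                n_hawks=self.n_hawks,
                max_iter=self.max_iter,
                seed=self.random_state,
            ),
        )
        self.solution_ = solution
        self.selected_indices_ = solution.gene_indices
        self.error_rate_ = solution.error_rate
        self.accuracy_ = solution.accuracy
        self.history_ = solution.history
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[solution.gene_indices] = True
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_
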
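"""Optional phase-1 gene pre-filter: relevance + redundancy ranking.

Before the wrapper search, genes can be reduced to a candidate pool by an
mRMR-style greedy ranking: per-gene one-way ANOVA F statistics measure
relevance to the class labels, and mean absolute Pearson correlation with
already-kept genes measures redundancy. The stage is OFF by default; with
it disabled the pipeline is identical to running the selector directly.

This filter is a reconstruction of a generically described
relevance/redundancy pre-processing phase — the concrete measures here
(ANOVA F, Pearson correlation, greedy difference criterion) are this
package's own documented choices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin, f_classif
from sklearn.utils.validation import check_is_fitted, validate_data

from .data import ExpressionDataset

__all__ = ["FilterResult", "relevance_scores", "mrmr_filter", "MRMRFilter"]


@dataclass
class FilterResult:
    """Outcome of the greedy relevance/redundancy ranking.

    ``kept_indices`` are in selection order (descending greedy criterion);
    ``relevance_scores`` covers every gene of the input dataset.
    """

    kept_indices: np.ndarray
    relevance_scores: np.ndarray
    redundancy_matrix: np.ndarray | None = field(default=None, repr=False)


def relevance_scores(dataset: ExpressionDataset) -> np.ndarray:
    """Per-gene one-way ANOVA F statistic of expression against class.

    Genes with zero variance everywhere score 0. A perfectly separating
    gene (zero within-class variance, nonzero between) scores +inf, which
    orders correctly in the greedy ranking.
    """
    y = dataset.label_codes()
    counts = np.bincount(y, minlength=dataset.n_classes)
    if counts.min() < 2:
        small = dataset.class_names[int(np.argmin(counts))]
        raise ValueError(
            f"class {small!r} has fewer than 2 samples; the ANOVA-F relevance "
            "filter is undefined — disable the pre-filter for this dataset"
        )
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Features .* are constant")
        f_stat, _ = f_classif(dataset.matrix, y)
    f_stat = np.asarray(f_stat, dtype=float)
    f_stat[np.isnan(f_stat)] = 0.0  # constant genes: 0/0 -> no relevance
    return f_stat


def _abs_corr_with(matrix: np.ndarray, col: np.ndarray) -> np.ndarray:
    """|Pearson r| of every column of ``matrix`` with ``col``; zero-variance
    pairs count as correlation 0."""
    xc = matrix - matrix.mean(axis=0)
    yc = col - col.mean()
    num = xc.T @ yc
    den = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return np.abs(r)


def mrmr_filter(
    dataset: ExpressionDataset,
    n_keep: int,
    with_redundancy_matrix: bool = False,
) -> FilterResult:
    """Greedy minimum-redundancy / maximum-relevance gene ranking.

    The first gene maximizes relevance; each subsequent gene maximizes
    relevance minus its mean absolute Pearson correlation with the genes
    already kept. Ties break toward the lower gene index. Deterministic.
    """
    if not 1 <= n_keep <= dataset.n_genes:
        raise ValueError(f"n_keep={n_keep} must be in [1, {dataset.n_genes}]")
    rel = relevance_scores(dataset)
    X = dataset.matrix
    n_genes = dataset.n_genes

    kept: list[int] = [int(np.argmax(rel))]  # argmax: ties -> lower index
    redundancy_sum = np.zeros(n_genes)
    available = np.ones(n_genes, dtype=bool)
    available[kept[0]] = False
    while len(kept) < n_keep:
        redundancy_sum += _abs_corr_with(X, X[:, kept[-1]])
        crit = rel - redundancy_sum / len(kept)
        crit[~available] = -np.inf
        nxt = int(np.argmax(crit))
        kept.append(nxt)
        available[nxt] = False

    kept_arr = np.array(kept, dtype=np.intp)
    red = None
    if with_redundancy_matrix:
        sub = X[:, kept_arr]
        with np.errstate(divide="ignore", invalid="ignore"):
            c = np.corrcoef(sub, rowvar=False)
        c = np.atleast_2d(np.nan_to_num(c, nan=0.0))
        red = np.abs(c)
    return FilterResult(kept_indices=kept_arr, relevance_scores=rel,
                        redundancy_matrix=red)


class MRMRFilter(SelectorMixin, BaseEstimator):
    """scikit-learn transformer exposing the greedy relevance/redundancy filter.

    Parameters
    ----------
    n_keep : int, default=100
        Number of genes to retain.

    Attributes
    ----------
    kept_indices_ : ndarray
        Selected columns in greedy order.
    relevance_scores_ : ndarray of shape (n_features,)
        ANOVA F statistic per gene.
    """

    def __init__(self, n_keep: int = 100):
        self.n_keep = n_keep

    def fit(self, X, y):
        X, y = validate_data(self, X, y, ensure_min_samples=2)
        y = np.asarray(y)
        dataset = ExpressionDataset(
            matrix=X,
            gene_ids=[f"g{j}" for j in range(X.shape[1])],
            labels=y.astype(str),
        )
        result = mrmr_filter(dataset, self.n_keep)
        self.kept_indices_ = result.kept_indices
        self.relevance_scores_ = result.relevance_scores
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[result.kept_indices] = True
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_
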
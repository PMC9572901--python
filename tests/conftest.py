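import numpy as np
import pytest

from hhoselect.data import ExpressionDataset


@pytest.fixture
def two_class_1d():
    """Four samples on one gene, trivially separated: (0, 0.1) A vs (1.0, 1.1) B."""
    return ExpressionDataset(
        matrix=np.array([[0.0], [0.1], [1.0], [1.1]]),
        gene_ids=["g0"],
        labels=np.array(["A", "A", "B", "B"], dtype=object),
    )


@pytest.fixture
def separable_dataset():
    """10 samples x 4 genes; gene 0 separates the classes with a wide margin,
    the rest are fixed pseudo-noise."""
    rng = np.random.default_rng(42)
    n = 10
    labels = np.array(["A"] * 5 + ["B"] * 5, dtype=object)
    matrix = rng.normal(size=(n, 4))
    matrix[:, 0] = np.where(labels == "A", 0.0, 10.0) + rng.normal(0, 0.1, n)
    return ExpressionDataset(
        matrix=matrix, gene_ids=[f"g{j}" for j in range(4)], labels=labels
    )


def make_dataset(matrix, labels, class_names=None):
    matrix = np.asarray(matrix, dtype=float)
    return ExpressionDataset(
        matrix=matrix,
        gene_ids=[f"g{j}" for j in range(matrix.shape[1])],
        labels=np.asarray(labels, dtype=object),
        class_names=class_names or [],
    )
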
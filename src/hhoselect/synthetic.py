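"""Synthetic labelled expression matrices with planted informative genes.

The generator emulates the shape of classic microarray benchmarks — tens
of samples, thousands of genes, 2-4 classes — with a transparent Gaussian
class-shift model: uninformative genes are i.i.d. Normal(0, noise_sd)
regardless of class, and each informative gene's class means are spaced
``effect_size * noise_sd`` apart. A log-normal option exponentiates the
matrix to mimic the right-skew of raw intensity data. Everything is a pure
function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ExpressionDataset

__all__ = ["SyntheticSpec", "generate", "make_expression"]


@dataclass
class SyntheticSpec:
    """Parameters of the planted-signal generator.

    effect_size is the spacing of adjacent class means in units of the
    within-class standard deviation; 0 plants no signal at all, and values
    around 3 give strongly but not trivially separable classes.
    """

    n_samples: int = 62
    n_genes: int = 2000
    n_classes: int = 2
    n_informative: int = 10
    effect_size: float = 3.0
    noise_sd: float = 1.0
    class_proportions: tuple[float, ...] | None = None
    lognormal: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not 0 <= self.n_informative <= self.n_genes:
            raise ValueError("need 0 <= n_informative <= n_genes")
        if self.n_samples < self.n_classes:
            raise ValueError("need at least one sample per class")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.class_proportions is not None:
            props = np.asarray(self.class_proportions, dtype=float)
            if props.size != self.n_classes or np.any(props <= 0):
                raise ValueError("class_proportions must be positive, one per class")
            if not np.isclose(props.sum(), 1.0):
                raise ValueError("class_proportions must sum to 1")


def _class_counts(spec: SyntheticSpec) -> np.ndarray:
    if spec.class_proportions is None:
        props = np.full(spec.n_classes, 1.0 / spec.n_classes)
    else:
        props = np.asarray(spec.class_proportions, dtype=float)
    # largest-remainder rounding so counts sum exactly to n_samples
    raw = props * spec.n_samples
    counts = np.floor(raw).astype(int)
    short = spec.n_samples - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:short]] += 1
    if counts.min() < 1:
        raise ValueError("class_proportions leave a class empty at this n_samples")
    return counts


def generate(spec: SyntheticSpec) -> tuple[ExpressionDataset, np.ndarray]:
    """Draw a dataset; returns (dataset, sorted truth indices of planted genes)."""
    rng = np.random.default_rng(spec.seed)
    counts = _class_counts(spec)
    codes = np.repeat(np.arange(spec.n_classes), counts)
    rng.shuffle(codes)

    matrix = rng.normal(0.0, spec.noise_sd, size=(spec.n_samples, spec.n_genes))
    truth = np.sort(
        rng.choice(spec.n_genes, size=spec.n_informative, replace=False)
    ).astype(np.intp)
    if spec.n_informative and spec.effect_size > 0:
        # centred class means spaced effect_size * noise_sd apart
        offsets = (codes - (spec.n_classes - 1) / 2.0) * spec.effect_size * spec.noise_sd
        matrix[:, truth] += offsets[:, np.newaxis]
    if spec.lognormal:
        matrix = np.exp(matrix)

    class_names = [f"c{c}" for c in range(spec.n_classes)]
    dataset = ExpressionDataset(
        matrix=matrix,
        gene_ids=[f"g{j}" for j in range(spec.n_genes)],
        labels=np.array([class_names[c] for c in codes], dtype=object),
        class_names=class_names,
    )
    return dataset, truth


def make_expression(**kwargs) -> tuple[ExpressionDataset, np.ndarray]:
    """Convenience wrapper: ``make_expression(n_samples=62, ...)``."""
    return generate(SyntheticSpec(**kwargs))
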
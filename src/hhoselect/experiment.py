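"""The evaluation protocol: repeated selection runs over a grid of subset
sizes and classifiers, summarized as best/average/worst accuracy.

Each (classifier, subset size) cell aggregates ``n_runs`` independent
searches whose seeds derive deterministically from the master seed and the
cell coordinates, so the whole protocol output is a pure function of
(dataset, configuration, seed) and is independent of grid traversal order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data import ExpressionDataset
from .fitness import FitnessSpec
from .hho import HHOParams
from .selection import SubsetSolution, select_genes

__all__ = ["RunSummary", "derive_run_seed", "run_protocol"]

logger = logging.getLogger(__name__)

_CLASSIFIER_CODE = {"knn": 0, "svm": 1}


@dataclass
class RunSummary:
    """Best/average/worst accuracy over repeated runs at one grid cell."""

    classifier: str
    n_selected: int
    n_runs: int
    best_acc: float
    average_acc: float
    worst_acc: float
    best_solution: SubsetSolution = field(repr=False)
    seeds: list[int] = field(default_factory=list, repr=False)
    seed: int | None = None  # master seed
    best_gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.worst_acc <= self.average_acc + 1e-12:
            raise ValueError("worst_acc must be <= average_acc")
        if not self.average_acc <= self.best_acc + 1e-12:
            raise ValueError("average_acc must be <= best_acc")


def derive_run_seed(master_seed: int, classifier: str, n_selected: int,
                    run_index: int) -> int:
    """Deterministic per-run seed, independent of grid traversal order.

    Seeds come from non-overlapping SeedSequence streams keyed by the cell
    coordinates; results stay below 2**31.
    """
    ss = np.random.SeedSequence(
        entropy=master_seed,
        spawn_key=(_CLASSIFIER_CODE[classifier], n_selected, run_index),
    )
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def run_protocol(
    dataset: ExpressionDataset,
    gene_counts,
    classifiers=("knn", "svm"),
    params: HHOParams | None = None,
    n_runs: int = 30,
    master_seed: int = 0,
    fitness_kwargs: dict | None = None,
) -> list[RunSummary]:
    """Run the full grid and return one :class:`RunSummary` per cell.

    Parameters
    ----------
    gene_counts : iterable of int
        Subset sizes to evaluate (the benchmark protocol uses 1..30).
    classifiers : iterable of {'knn', 'svm'}
    params : HHOParams, optional
        Optimizer settings; ``dim`` is forced to ``n_genes`` and the seed
        is replaced per run. Defaults: 10 hawks, 100 iterations.
    n_runs : int, default=30
        Independent repetitions per cell.
    master_seed : int
        Root of the per-run seed derivation.
    fitness_kwargs : dict, optional
        Extra :class:`FitnessSpec` fields (k_neighbors, svm_kernel, ...).
    """
    gene_counts = [int(g) for g in gene_counts]
    classifiers = list(classifiers)
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    for g in gene_counts:
        if not 1 <= g <= dataset.n_genes:
            raise ValueError(
                f"subset size {g} outside [1, {dataset.n_genes}] (number of genes)"
            )
    for clf in classifiers:
        if clf not in _CLASSIFIER_CODE:
            raise ValueError(f"unknown classifier {clf!r}")
    if params is None:
        params = HHOParams(dim=dataset.n_genes)
    fitness_kwargs = dict(fitness_kwargs or {})

    summaries: list[RunSummary] = []
    for clf in classifiers:
        spec = FitnessSpec(classifier=clf, **fitness_kwargs)
        for n_sel in gene_counts:
            accs: list[float] = []
            seeds: list[int] = []
            best_solution: SubsetSolution | None = None
            for r in range(n_runs):
                run_seed = derive_run_seed(master_seed, clf, n_sel, r)
                seeds.append(run_seed)
                run_params = HHOParams(
                    dim=dataset.n_genes,
                    n_hawks=params.n_hawks,
                    max_iter=params.max_iter,
                    lb=params.lb,
                    ub=params.ub,
                    seed=run_seed,
                )
                sol = select_genes(dataset, n_sel, spec, run_params)
                accs.append(sol.accuracy)
                if best_solution is None or sol.accuracy > best_solution.accuracy:
                    best_solution = sol
                logger.debug(
                    "protocol %s n_sel=%d run=%d seed=%d acc=%.4f",
                    clf, n_sel, r, run_seed, sol.accuracy,
                )
            summaries.append(
                RunSummary(
                    classifier=clf,
                    n_selected=n_sel,
                    n_runs=n_runs,
                    best_acc=float(max(accs)),
                    # clamp: float summation error must not break the
                    # worst <= average <= best ordering invariant
                    average_acc=float(min(max(np.mean(accs), min(accs)), max(accs))),
                    worst_acc=float(min(accs)),
                    best_solution=best_solution,
                    seeds=seeds,
                    seed=master_seed,
                    best_gene_ids=[dataset.gene_ids[i]
                                   for i in best_solution.gene_indices],
                )
            )
    return summaries
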
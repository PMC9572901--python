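"""Harris Hawks Optimization over a continuous box.

HHO is a population metaheuristic modelled on cooperative hawk hunting:
candidate solutions ("hawks") pursue the best solution found so far (the
"rabbit"). A scalar escaping energy E, decaying linearly over iterations,
switches the search between exploration (|E| >= 1) and four exploitation
modes — soft siege, hard siege, and "progressive rapid dive" variants of
each that perturb a candidate with Levy-flight steps and accept moves
greedily. The optimizer minimizes an arbitrary callable over [lb, ub]^dim.

Conventions fixed here (the published update rules leave them open):

* positions are clipped coordinate-wise to the box after every update;
* the rabbit is refreshed immediately after each fitness evaluation, and
  keeps the incumbent on exact ties;
* the iteration clock runs t = 1..max_iter inside the energy formula, so
  E = 0 exactly in the final iteration and no exploration occurs there;
* all stochastic scalars (q, p, r1..r4, e0) are redrawn per hawk per
  iteration from a single seeded stream, making runs fully deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "HHOParams",
    "HawkPopulation",
    "HHOResult",
    "initialize_population",
    "escape_energy",
    "jump_strength",
    "mean_position",
    "exploration_step",
    "soft_siege_step",
    "hard_siege_step",
    "levy_step",
    "soft_siege_dives",
    "hard_siege_dives",
    "hho_minimize",
]

Objective = Callable[[np.ndarray], float]

LEVY_BETA = 1.5
LEVY_SCALE = 0.01


@dataclass
class HHOParams:
    """Optimizer configuration.

    Defaults follow the standard benchmark settings for this method:
    10 hawks, 100 iterations, unit box [0, 1].
    """

    dim: int
    n_hawks: int = 10
    max_iter: int = 100
    lb: float = 0.0
    ub: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.n_hawks < 2:
            raise ValueError("n_hawks must be >= 2")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not self.lb < self.ub:
            raise ValueError(f"need lb < ub, got [{self.lb}, {self.ub}]")


@dataclass
class HawkPopulation:
    positions: np.ndarray  # (n_hawks, dim)
    fitnesses: np.ndarray  # (n_hawks,)
    rabbit_position: np.ndarray
    rabbit_fitness: float
    iteration: int = 0


@dataclass
class HHOResult:
    best_position: np.ndarray
    best_fitness: float
    history: np.ndarray  # per-iteration rabbit fitness, length max_iter
    n_evaluations: int
    params: HHOParams = field(repr=False, default=None)


def _clip(x: np.ndarray, params: HHOParams) -> np.ndarray:
    return np.clip(x, params.lb, params.ub)


def _check_fitness(value: float) -> float:
    value = float(value)
    if math.isnan(value):
        raise ValueError("objective returned NaN")
    return value


def initialize_population(params: HHOParams, fitness: Objective,
                          rng: np.random.Generator | None = None) -> HawkPopulation:
    """Sample hawks i.i.d. uniform on the box and evaluate them."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    positions = rng.uniform(params.lb, params.ub, size=(params.n_hawks, params.dim))
    fitnesses = np.array([_check_fitness(fitness(p)) for p in positions])
    best = int(np.argmin(fitnesses))
    return HawkPopulation(
        positions=positions,
        fitnesses=fitnesses,
        rabbit_position=positions[best].copy(),
        rabbit_fitness=float(fitnesses[best]),
    )


def escape_energy(e0: float, t: int, max_iter: int) -> float:
    """Escaping energy E = 2*e0*(1 - t/max_iter); decays linearly to 0."""
    if t > max_iter:
        raise ValueError(f"t={t} exceeds max_iter={max_iter}")
    if t < 0:
        raise ValueError("t must be >= 0")
    return 2.0 * e0 * (1.0 - t / max_iter)


def jump_strength(r: float) -> float:
    """Rabbit's random jump force J = 2*(1 - r), strictly in (0, 2) for r in (0, 1)."""
    return 2.0 * (1.0 - r)


def mean_position(population: HawkPopulation) -> np.ndarray:
    """Coordinate-wise arithmetic mean of the hawks' positions."""
    return population.positions.mean(axis=0)


def exploration_step(
    x: np.ndarray,
    x_random: np.ndarray,
    x_rabbit: np.ndarray,
    x_mean: np.ndarray,
    q: float,
    r1: float,
    r2: float,
    r3: float,
    r4: float,
    params: HHOParams,
) -> np.ndarray:
    """Exploration move: perch on a random hawk (q >= 0.5) or near the
    rabbit relative to the population mean (q < 0.5)."""
    if q >= 0.5:
        new = x_random - r1 * np.abs(x_random - 2.0 * r2 * x)
    else:
        new = (x_rabbit - x_mean) - r3 * (params.lb + r4 * (params.ub - params.lb))
    return _clip(new, params)


def soft_siege_step(
    x: np.ndarray, x_rabbit: np.ndarray, e: float, j: float, params: HHOParams
) -> np.ndarray:
    """Soft siege (|E| in [0.5, 1)): circle the prey, which still has energy."""
    delta = x_rabbit - x
    return _clip(delta - e * np.abs(j * x_rabbit - x), params)


def hard_siege_step(
    x: np.ndarray, x_rabbit: np.ndarray, e: float, params: HHOParams
) -> np.ndarray:
    """Hard siege (|E| < 0.5): close in directly on the exhausted prey."""
    delta = x_rabbit - x
    return _clip(x - e * np.abs(delta), params)


def _mantegna_sigma(beta: float) -> float:
    num = math.gamma(1 + beta) * math.sin(math.pi * beta / 2)
    den = math.gamma((1 + beta) / 2) * beta * 2 ** ((beta - 1) / 2)
    return (num / den) ** (1 / beta)


_SIGMA_U = _mantegna_sigma(LEVY_BETA)


def levy_step(dim: int, rng: np.random.Generator) -> np.ndarray:
    """Additive dive perturbation: uniform random vector times Levy steps.

    Heavy-tailed steps come from Mantegna's algorithm with stability
    exponent beta = 1.5, scaled by 0.01; the elementwise uniform factor
    matches the reference construction of the rapid-dive update.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    u = rng.normal(0.0, _SIGMA_U, size=dim)
    v = rng.normal(0.0, 1.0, size=dim)
    levy = LEVY_SCALE * u / np.abs(v) ** (1.0 / LEVY_BETA)
    return rng.uniform(size=dim) * levy


def _greedy_dive(
    x: np.ndarray,
    f_x: float,
    k: np.ndarray,
    fitness: Objective,
    params: HHOParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float, int]:
    """Greedy acceptance of dive candidates: try k, then the Levy dive z;
    keep x if neither strictly improves. Returns (position, fitness, n_evals)."""
    k = _clip(k, params)
    f_k = _check_fitness(fitness(k))
    if f_k < f_x:
        return k, f_k, 1
    z = _clip(k + levy_step(params.dim, rng), params)
    f_z = _check_fitness(fitness(z))
    if f_z < f_x:
        return z, f_z, 2
    return x, f_x, 2


def soft_siege_dives(
    x: np.ndarray,
    x_rabbit: np.ndarray,
    e: float,
    j: float,
    fitness: Objective,
    params: HHOParams,
    rng: np.random.Generator,
    f_x: float | None = None,
) -> np.ndarray:
    """Soft siege with progressive rapid dives (|E| >= 0.5, p < 0.5)."""
    if f_x is None:
        f_x = _check_fitness(fitness(x))
    k = x_rabbit - e * np.abs(j * x_rabbit - x)
    new, _, _ = _greedy_dive(x, f_x, k, fitness, params, rng)
    return new


def hard_siege_dives(
    x: np.ndarray,
    x_rabbit: np.ndarray,
    x_mean: np.ndarray,
    e: float,
    j: float,
    fitness: Objective,
    params: HHOParams,
    rng: np.random.Generator,
    f_x: float | None = None,
) -> np.ndarray:
    """Hard siege with progressive rapid dives (|E| < 0.5, p < 0.5);
    the first candidate is anchored on the population mean."""
    if f_x is None:
        f_x = _check_fitness(fitness(x))
    k = x_rabbit - e * np.abs(j * x_rabbit - x_mean)
    new, _, _ = _greedy_dive(x, f_x, k, fitness, params, rng)
    return new


def hho_minimize(
    fitness: Objective,
    params: HHOParams,
    callback: Callable[[int, float, int], None] | None = None,
) -> HHOResult:
    """Run HHO for ``params.max_iter`` iterations and return the rabbit.

    ``callback(iteration, rabbit_fitness, n_evaluations)`` is invoked once
    per iteration (useful for logging convergence).
    """
    rng = np.random.default_rng(params.seed)
    pop = initialize_population(params, fitness, rng)
    n_evals = params.n_hawks
    history = np.empty(params.max_iter)

    for t in range(1, params.max_iter + 1):
        x_mean = mean_position(pop)
        for i in range(params.n_hawks):
            x = pop.positions[i]
            f_x = float(pop.fitnesses[i])
            e0 = rng.uniform(-1.0, 1.0)
            e = escape_energy(e0, t, params.max_iter)
            p = rng.uniform()
            q = rng.uniform()
            r1, r2, r3, r4 = rng.uniform(size=4)

            if abs(e) >= 1.0:
                idx = int(rng.integers(params.n_hawks))
                new = exploration_step(
                    x, pop.positions[idx], pop.rabbit_position, x_mean,
                    q, r1, r2, r3, r4, params,
                )
                f_new = _check_fitness(fitness(new))
                n_evals += 1
            else:
                j = jump_strength(rng.uniform())
                if p >= 0.5:
                    if abs(e) >= 0.5:
                        new = soft_siege_step(x, pop.rabbit_position, e, j, params)
                    else:
                        new = hard_siege_step(x, pop.rabbit_position, e, params)
                    f_new = _check_fitness(fitness(new))
                    n_evals += 1
                else:
                    if abs(e) >= 0.5:
                        k = pop.rabbit_position - e * np.abs(
                            j * pop.rabbit_position - x
                        )
                    else:
                        k = pop.rabbit_position - e * np.abs(
                            j * pop.rabbit_position - x_mean
                        )
                    new, f_new, used = _greedy_dive(x, f_x, k, fitness, params, rng)
                    n_evals += used

            pop.positions[i] = new
            pop.fitnesses[i] = f_new
            if f_new < pop.rabbit_fitness:
                pop.rabbit_fitness = f_new
                pop.rabbit_position = new.copy()

        pop.iteration = t
        history[t - 1] = pop.rabbit_fitness
        if callback is not None:
            callback(t, pop.rabbit_fitness, n_evals)

    return HHOResult(
        best_position=pop.rabbit_position.copy(),
        best_fitness=float(pop.rabbit_fitness),
        history=history,
        n_evaluations=n_evals,
        params=params,
    )
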
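"""Harris Hawks Optimization (HHO) over a bounded continuous search space.

HHO is a population metaheuristic that mimics the cooperative hunting of
Harris' hawks.  A population of N "hawks" (candidate solutions) chases a
"rabbit" (the best solution found so far).  Each iteration every hawk draws
a fresh escape energy ``E = 2*E0*(1 - t/T)`` with ``E0 ~ U(-1, 1)``:

* ``|E| >= 1`` — exploration: random perching relative to a random hawk or
  to the rabbit and the population mean;
* ``|E| >= 0.5`` (exploitation) — *soft besiege*, a jump-strength weighted
  pursuit of the rabbit;
* ``|E| < 0.5`` — *hard besiege*, a direct collapse onto the rabbit;
* with probability 1/2 either besiege is replaced by a *progressive rapid
  dive* that proposes two candidates (one deterministic, one perturbed by a
  heavy-tailed Levy flight) and keeps a candidate only if it improves on
  the hawk's current fitness.

The objective is a callable mapping a length-D position to a finite scalar
to be minimised.  All randomness flows through a single
``numpy.random.Generator`` so runs are reproducible from the seed alone.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "SearchSpace",
    "HhoConfig",
    "HawkPopulation",
    "OptimizationResult",
    "init_population",
    "mean_position",
    "escape_energy",
    "levy_step",
    "exploration_move",
    "soft_besiege_move",
    "hard_besiege_move",
    "soft_besiege_dive",
    "hard_besiege_dive",
    "hho_optimize",
    "hho_optimizer",
]

logger = logging.getLogger(__name__)

Objective = Callable[[np.ndarray], float]


class ObjectiveError(RuntimeError):
    """Raised when the objective returns a non-finite value or fails."""


@dataclass(frozen=True)
class SearchSpace:
    """Axis-aligned box of decision variables: ``lower <= x <= upper``."""

    lower: np.ndarray
    upper: np.ndarray

    def __init__(self, lower: Sequence[float], upper: Sequence[float]):
        lo = np.atleast_1d(np.asarray(lower, dtype=float))
        hi = np.atleast_1d(np.asarray(upper, dtype=float))
        if lo.shape != hi.shape or lo.ndim != 1 or lo.size < 1:
            raise ValueError("lower and upper must be 1-D vectors of equal length")
        if not np.all(lo < hi):
            raise ValueError("every lower bound must be strictly below its upper bound")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    @property
    def dim(self) -> int:
        return self.lower.size

    def clip(self, x: np.ndarray) -> np.ndarray:
        """Repair an out-of-box position by coordinate-wise clipping."""
        return np.clip(np.asarray(x, dtype=float), self.lower, self.upper)

    def sample(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        return rng.uniform(self.lower, self.upper, size=(n, self.dim))

    def contains(self, x: np.ndarray) -> bool:
        return bool(np.all(x >= self.lower) and np.all(x <= self.upper))


@dataclass(frozen=True)
class HhoConfig:
    """Run-length and population settings.

    Defaults follow the common benchmarking setup for this optimizer:
    30 hawks, 50 iterations, Levy exponent beta = 1.5.
    """

    n_hawks: int = 30
    max_iter: int = 50
    beta: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hawks < 2:
            raise ValueError("n_hawks must be >= 2")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not 0.0 < self.beta <= 2.0:
            raise ValueError("beta must lie in (0, 2]")


@dataclass
class HawkPopulation:
    """Positions and fitness of the hawks plus the best-so-far rabbit."""

    positions: np.ndarray  # N x D
    fitness: np.ndarray  # length N
    rabbit_position: np.ndarray
    rabbit_fitness: float

    @property
    def n_hawks(self) -> int:
        return self.positions.shape[0]

    def update_rabbit(self, position: np.ndarray, fitness: float) -> None:
        if fitness < self.rabbit_fitness:
            self.rabbit_position = position.copy()
            self.rabbit_fitness = float(fitness)


@dataclass
class OptimizationResult:
    best_position: np.ndarray
    best_fitness: float
    convergence: np.ndarray  # best-so-far after each iteration
    n_evals: int
    elapsed: float


def _evaluate(objective: Objective, x: np.ndarray, context: str) -> float:
    try:
        value = float(objective(x))
    except Exception as exc:  # re-raise with location information
        raise ObjectiveError(f"objective raised during {context} at {x!r}") from exc
    return value


def init_population(
    space: SearchSpace, cfg: HhoConfig, rng: np.random.Generator, objective: Objective
) -> tuple[HawkPopulation, int]:
    """Draw N uniform positions, evaluate each once, set the rabbit.

    Returns the population and the number of objective evaluations spent.
    """
    positions = space.sample(rng, cfg.n_hawks)
    fitness = np.empty(cfg.n_hawks)
    for i in range(cfg.n_hawks):
        fitness[i] = _evaluate(objective, positions[i], "initialization")
        if not math.isfinite(fitness[i]):
            raise ObjectiveError(
                f"non-finite objective value {fitness[i]} at initial position {positions[i]!r}"
            )
    best = int(np.argmin(fitness))
    pop = HawkPopulation(
        positions=positions,
        fitness=fitness,
        rabbit_position=positions[best].copy(),
        rabbit_fitness=float(fitness[best]),
    )
    return pop, cfg.n_hawks


def mean_position(population: HawkPopulation) -> np.ndarray:
    """Per-dimension arithmetic mean of the hawk positions."""
    if population.n_hawks < 1:
        raise ValueError("population is empty")
    return population.positions.mean(axis=0)


def escape_energy(e0: float, t: int, max_iter: int) -> float:
    """Prey escape energy ``2*E0*(1 - t/T)``, decaying linearly to 0 at t=T."""
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if not 0 <= t <= max_iter:
        raise ValueError("iteration index out of range")
    return 2.0 * e0 * (1.0 - t / max_iter)


def levy_scale(beta: float) -> float:
    """Mantegna scale constant for Levy-flight steps at exponent ``beta``."""
    num = math.gamma(1.0 + beta) * math.sin(math.pi * beta / 2.0)
    den = math.gamma((1.0 + beta) / 2.0) * beta * 2.0 ** ((beta - 1.0) / 2.0)
    return (num / den) ** (1.0 / beta)


def levy_step(dim: int, beta: float, rng: np.random.Generator) -> np.ndarray:
    """Heavy-tailed random step, component-wise ``0.01 * u * sigma / |v|^(1/beta)``.

    ``u`` and ``v`` are fresh uniform draws on [0, 1]; a ``v`` drawn exactly
    zero is redrawn so the step is always finite.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    if beta <= 0:
        raise ValueError("beta must be positive")
    sigma = levy_scale(beta)
    u = rng.random(dim)
    v = rng.random(dim)
    while np.any(v == 0.0):  # redraw rather than divide by zero
        v[v == 0.0] = rng.random(np.count_nonzero(v == 0.0))
    return 0.01 * u * sigma / np.abs(v) ** (1.0 / beta)


def exploration_move(
    hawk: np.ndarray,
    rand_hawk: np.ndarray,
    rabbit: np.ndarray,
    mean_pos: np.ndarray,
    space: SearchSpace,
    rng: np.random.Generator,
) -> np.ndarray:
    """Random perching: around a random hawk, or between rabbit and flock mean."""
    q = rng.random()
    if q >= 0.5:
        r1, r2 = rng.random(), rng.random()
        new = rand_hawk - r1 * np.abs(rand_hawk - 2.0 * r2 * hawk)
    else:
        r3, r4 = rng.random(), rng.random()
        new = (rabbit - mean_pos) - r3 * (space.lower + r4 * (space.upper - space.lower))
    return space.clip(new)


def soft_besiege_move(hawk: np.ndarray, rabbit: np.ndarray, e: float, j: float) -> np.ndarray:
    """Soft besiege: pursue the rabbit with jump-strength weighted distance."""
    delta = rabbit - hawk
    return delta - e * np.abs(j * rabbit - hawk)


def hard_besiege_move(hawk: np.ndarray, rabbit: np.ndarray, e: float) -> np.ndarray:
    """Hard besiege: collapse onto the rabbit scaled by the remaining energy."""
    return rabbit - e * np.abs(rabbit - hawk)


def _greedy_dive(
    y: np.ndarray,
    hawk: np.ndarray,
    hawk_fitness: float,
    objective: Objective,
    space: SearchSpace,
    rng: np.random.Generator,
    beta: float,
    context: str,
) -> tuple[np.ndarray, float, int]:
    """Shared greedy Y/Z candidate logic of both dive branches.

    Evaluates both candidates (2 objective calls); a candidate is adopted
    only when strictly better than the hawk's current fitness, Y taking
    precedence.  Non-finite candidate values are rejected, never adopted.
    """
    y = space.clip(y)
    s = rng.random(hawk.size)
    z = space.clip(y + s * levy_step(hawk.size, beta, rng))
    fy = _evaluate(objective, y, context)
    fz = _evaluate(objective, z, context)
    if not math.isfinite(fy):
        logger.warning("rejecting non-finite dive candidate Y at %r", y)
        fy = math.inf
    if not math.isfinite(fz):
        logger.warning("rejecting non-finite dive candidate Z at %r", z)
        fz = math.inf
    if fy < hawk_fitness:
        return y, fy, 2
    if fz < hawk_fitness:
        return z, fz, 2
    return hawk.copy(), hawk_fitness, 2


def soft_besiege_dive(
    hawk: np.ndarray,
    hawk_fitness: float,
    rabbit: np.ndarray,
    e: float,
    j: float,
    objective: Objective,
    space: SearchSpace,
    rng: np.random.Generator,
    beta: float = 1.5,
) -> tuple[np.ndarray, float, int]:
    """Soft besiege with progressive rapid dives (Levy-flight assisted)."""
    y = rabbit - e * np.abs(j * rabbit - hawk)
    return _greedy_dive(y, hawk, hawk_fitness, objective, space, rng, beta, "soft dive")


def hard_besiege_dive(
    hawk: np.ndarray,
    hawk_fitness: float,
    rabbit: np.ndarray,
    mean_pos: np.ndarray,
    e: float,
    j: float,
    objective: Objective,
    space: SearchSpace,
    rng: np.random.Generator,
    beta: float = 1.5,
) -> tuple[np.ndarray, float, int]:
    """Hard besiege with progressive rapid dives, aimed via the flock mean."""
    y = rabbit - e * np.abs(j * rabbit - mean_pos)
    return _greedy_dive(y, hawk, hawk_fitness, objective, space, rng, beta, "hard dive")


def hho_optimize(
    objective: Objective, space: SearchSpace, cfg: HhoConfig
) -> OptimizationResult:
    """Run HHO for ``cfg.max_iter`` iterations and return the best solution.

    Per hawk and iteration a fresh ``E0 ~ U(-1, 1)`` is drawn and the branch
    is selected on ``|E|`` (explore vs. besiege) and a fair coin ``r`` (plain
    besiege vs. rapid dive).  Non-dive branches overwrite the hawk position
    unconditionally; only the rabbit is elitist.  The rabbit is refreshed
    immediately after every evaluation, so the recorded convergence curve is
    monotone non-increasing.
    """
    start = time.perf_counter()
    rng = np.random.default_rng(cfg.seed)
    pop, n_evals = init_population(space, cfg, rng, objective)
    convergence = np.empty(cfg.max_iter)

    for t in range(cfg.max_iter):
        x_mean = mean_position(pop)
        for i in range(cfg.n_hawks):
            hawk = pop.positions[i]
            e0 = 2.0 * rng.random() - 1.0
            e = escape_energy(e0, t, cfg.max_iter)
            if abs(e) >= 1.0:
                rand_hawk = pop.positions[rng.integers(cfg.n_hawks)]
                new = exploration_move(hawk, rand_hawk, pop.rabbit_position, x_mean, space, rng)
                fit = _evaluate(objective, new, f"iteration {t}")
                n_evals += 1
            else:
                r = rng.random()
                j = 2.0 * (1.0 - rng.random())
                if r >= 0.5 and abs(e) >= 0.5:
                    new = space.clip(soft_besiege_move(hawk, pop.rabbit_position, e, j))
                    fit = _evaluate(objective, new, f"iteration {t}")
                    n_evals += 1
                elif r >= 0.5:
                    new = space.clip(hard_besiege_move(hawk, pop.rabbit_position, e))
                    fit = _evaluate(objective, new, f"iteration {t}")
                    n_evals += 1
                elif abs(e) >= 0.5:
                    new, fit, spent = soft_besiege_dive(
                        hawk, pop.fitness[i], pop.rabbit_position, e, j,
                        objective, space, rng, cfg.beta,
                    )
                    n_evals += spent
                else:
                    new, fit, spent = hard_besiege_dive(
                        hawk, pop.fitness[i], pop.rabbit_position, x_mean, e, j,
                        objective, space, rng, cfg.beta,
                    )
                    n_evals += spent
            pop.positions[i] = new
            pop.fitness[i] = fit
            pop.update_rabbit(new, fit)
        convergence[t] = pop.rabbit_fitness

    return OptimizationResult(
        best_position=pop.rabbit_position.copy(),
        best_fitness=float(pop.rabbit_fitness),
        convergence=convergence,
        n_evals=n_evals,
        elapsed=time.perf_counter() - start,
    )


def hho_optimizer(
    objective: Objective,
    space: SearchSpace,
    budget: tuple[int, int],
    seed: int,
) -> OptimizationResult:
    """Plug-in adapter: ``budget = (n_agents, max_iter)``."""
    n_agents, max_iter = budget
    return hho_optimize(objective, space, HhoConfig(n_hawks=n_agents, max_iter=max_iter, seed=seed))
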
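"""Continuous sunflower optimisation over a bounded box.

Population candidates ("sunflowers") orient toward the incumbent best
("sun") with distance-dependent steps capped by a per-dimension maximum,
recombine locally (pollination) and are periodically culled and replaced
with fresh uniform samples (elimination).  Generic over any maximized
fitness callable ``position -> float``; minimize by negating.

Conventions (logged once per run): the sun never moves (elitism); ties
break to the lowest index; positions are clamped, not reflected, at box
edges; pollination count is ``ceil(rate * N)`` and elimination count is
``floor(rate * N)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SfoaConfig",
    "Population",
    "SfoaResult",
    "initialize_population",
    "find_sun",
    "orientation",
    "max_step",
    "step_and_update",
    "pollinate",
    "eliminate_and_replace",
    "optimize",
]

FitnessFn = Callable[[np.ndarray], float]


@dataclass
class SfoaConfig:
    """Run parameters for one optimisation process.

    ``phi`` (inertia) scales the neighbour-distance step magnitude; the
    step is always truncated at the per-dimension cap
    ``(upper - lower) / (2 N)``.  The default is large on purpose: with
    the cap binding, non-sun individuals hover around the incumbent at
    cap scale, which empirically refines solutions much faster than a
    slow crawl (small ``phi`` recovers the crawl).
    """

    lower: np.ndarray
    upper: np.ndarray
    population: int = 30
    pollination_rate: float = 0.025
    elimination_rate: float = 0.20
    iterations: int = 300
    phi: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.lower = np.atleast_1d(np.asarray(self.lower, dtype=float))
        self.upper = np.atleast_1d(np.asarray(self.upper, dtype=float))
        if self.lower.shape != self.upper.shape:
            raise ValueError("box bounds must have equal shape")
        if not np.all(self.lower < self.upper):
            raise ValueError("box requires lower < upper in every dimension")
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if not (0 <= self.pollination_rate < 1 and 0 <= self.elimination_rate < 1):
            raise ValueError("rates must lie in [0, 1)")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")

    @property
    def dim(self) -> int:
        return self.lower.size


@dataclass
class Population:
    positions: np.ndarray  # (N, D)
    fitness: np.ndarray  # (N,)

    @property
    def size(self) -> int:
        return self.positions.shape[0]


@dataclass
class SfoaResult:
    best_position: np.ndarray
    best_fitness: float
    history: list[float]  # best-so-far per iteration
    population: Population
    n_evaluations: int = 0


def initialize_population(
    config: SfoaConfig, rng: np.random.Generator, fitness_fn: FitnessFn
) -> Population:
    """N i.i.d. uniform positions in the box, fitness evaluated."""
    pos = rng.uniform(config.lower, config.upper, size=(config.population, config.dim))
    fit = np.array([fitness_fn(p) for p in pos], dtype=float)
    return Population(pos, fit)


def find_sun(fitness: np.ndarray | Sequence[float]) -> int:
    """Index of the best (maximum) fitness; ties go to the lowest index."""
    return int(np.argmax(np.asarray(fitness)))


def orientation(sun: np.ndarray, individual: np.ndarray) -> tuple[np.ndarray, bool]:
    """Unit vector from ``individual`` toward ``sun``.

    Returns ``(vector, at_sun)``; when the individual sits exactly at the
    sun the vector is zero and ``at_sun`` is True ("sun holds position").
    """
    diff = np.asarray(sun, dtype=float) - np.asarray(individual, dtype=float)
    norm = float(np.linalg.norm(diff))
    if norm == 0.0:
        return np.zeros_like(diff), True
    return diff / norm, False


def max_step(lower: np.ndarray, upper: np.ndarray, n_pop: int) -> np.ndarray:
    """Per-dimension step cap ``(upper - lower) / (2 N)``."""
    if n_pop < 1:
        raise ValueError("population must be >= 1")
    return (np.atleast_1d(np.asarray(upper, float)) - np.atleast_1d(np.asarray(lower, float))) / (
        2.0 * n_pop
    )


def step_and_update(
    pop: Population,
    sun_idx: int,
    config: SfoaConfig,
    fitness_fn: FitnessFn,
    rng: np.random.Generator | None = None,
) -> int:
    """Move every non-sun individual toward the sun; returns evaluation count.

    The scalar step for individual ``i`` is ``phi * P_i * ||x_i - x_{i-1}||``
    (cyclic neighbour) where ``P_i ~ U(0.5, 1.5)`` is a stochastic
    pollination-probability weight (``P_i = 1`` when no ``rng`` is given),
    applied along the unit orientation and truncated per dimension at the
    cap; positions are clamped to the box.  The sun is left in place, so
    the population best never degrades.
    """
    d_max = max_step(config.lower, config.upper, pop.size)
    sun_pos = pop.positions[sun_idx].copy()
    n_eval = 0
    for i in range(pop.size):
        if i == sun_idx:
            continue
        direction, at_sun = orientation(sun_pos, pop.positions[i])
        if at_sun:
            continue
        prev = pop.positions[i - 1] if i > 0 else pop.positions[pop.size - 1]
        weight = rng.uniform(0.5, 1.5) if rng is not None else 1.0
        s_i = config.phi * weight * float(np.linalg.norm(pop.positions[i] - prev))
        disp = np.clip(s_i * direction, -d_max, d_max)
        pop.positions[i] = np.clip(pop.positions[i] + disp, config.lower, config.upper)
        pop.fitness[i] = fitness_fn(pop.positions[i])
        n_eval += 1
    return n_eval


def pollinate(
    pop: Population,
    sun_idx: int,
    config: SfoaConfig,
    fitness_fn: FitnessFn,
    rng: np.random.Generator,
) -> int:
    """Local recombination near the sun; returns evaluation count.

    The ``ceil(rate * N)`` non-sun individuals closest to the sun each
    produce one offspring uniform on the segment to their next-ranked
    neighbour; offspring replace the equally many worst individuals
    (never the sun).
    """
    k = int(np.ceil(config.pollination_rate * pop.size))
    if k == 0:
        return 0
    dist = np.linalg.norm(pop.positions - pop.positions[sun_idx], axis=1)
    order = [i for i in np.argsort(dist, kind="stable") if i != sun_idx]
    k = min(k, len(order) - 1)
    if k <= 0:
        return 0
    offspring = np.empty((k, config.dim))
    for r in range(k):
        parent, neighbour = pop.positions[order[r]], pop.positions[order[r + 1]]
        u = rng.uniform()
        offspring[r] = u * parent + (1.0 - u) * neighbour
    worst = [i for i in np.argsort(pop.fitness, kind="stable") if i != sun_idx][:k]
    for slot, child in zip(worst, offspring):
        pop.positions[slot] = child
        pop.fitness[slot] = fitness_fn(child)
    return k


def eliminate_and_replace(
    pop: Population,
    sun_idx: int,
    config: SfoaConfig,
    fitness_fn: FitnessFn,
    rng: np.random.Generator,
    iteration: int = 0,
) -> int:
    """Replace the ``floor(rate * N)`` worst individuals (never the sun)
    with fresh uniform samples; returns evaluation count.

    ``iteration`` is accepted for schedule experiments but the default
    policy is constant-rate.
    """
    k = int(np.floor(config.elimination_rate * pop.size))
    if k == 0:
        return 0
    worst = [i for i in np.argsort(pop.fitness, kind="stable") if i != sun_idx][:k]
    fresh = rng.uniform(config.lower, config.upper, size=(len(worst), config.dim))
    for slot, pos in zip(worst, fresh):
        pop.positions[slot] = pos
        pop.fitness[slot] = fitness_fn(pos)
    return len(worst)


def optimize(
    fitness_fn: FitnessFn,
    config: SfoaConfig,
    callback: Callable[[int, Population, float], None] | None = None,
) -> SfoaResult:
    """Run the full loop: init, then per iteration find sun -> step ->
    pollinate -> eliminate.  Deterministic for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    pop = initialize_population(config, rng, fitness_fn)
    n_eval = pop.size
    best_idx = find_sun(pop.fitness)
    best_pos = pop.positions[best_idx].copy()
    best_fit = float(pop.fitness[best_idx])
    history: list[float] = []
    for it in range(config.iterations):
        sun_idx = find_sun(pop.fitness)
        n_eval += step_and_update(pop, sun_idx, config, fitness_fn, rng)
        n_eval += pollinate(pop, sun_idx, config, fitness_fn, rng)
        n_eval += eliminate_and_replace(pop, sun_idx, config, fitness_fn, rng, it)
        cur_idx = find_sun(pop.fitness)
        if pop.fitness[cur_idx] > best_fit:
            best_fit = float(pop.fitness[cur_idx])
            best_pos = pop.positions[cur_idx].copy()
        history.append(best_fit)
        if callback is not None:
            callback(it, pop, best_fit)
    return SfoaResult(best_pos, best_fit, history, pop, n_eval)
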
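"""Simulated annealing with exponential, linear and logarithmic cooling.

A population is treated as independent annealing chains: every chain
proposes a Gaussian perturbation of its current point each generation and
accepts it by the Metropolis rule at the scheduled temperature. The cooling
factor trades exploration (slow cooling) against exploitation (fast).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ConfigurationError
from .base import Optimizer

__all__ = ["SAConfig", "sa_accept", "sa_step", "cooling", "SAOptimizer"]


@dataclass(frozen=True)
class SAConfig:
    schedule: str = "exponential"   # "exponential" | "linear" | "logarithmic"
    initial_temperature: float = 1.0
    cooling_factor: float = 0.98    # exponential decay base / linear slope share
    step_scale: float = 0.1         # proposal noise scale

    def __post_init__(self):
        if not self.initial_temperature > 0:
            raise ConfigurationError("initial temperature must be > 0")
        if self.schedule not in ("exponential", "linear", "logarithmic"):
            raise ConfigurationError(f"unknown schedule {self.schedule!r}")
        if not 0 < self.cooling_factor <= 1:
            raise ConfigurationError("cooling_factor must lie in (0, 1]")


def cooling(kind: str, generation: int, config: SAConfig) -> float:
    """Temperature at a given generation (always > 0).

    exponential: ``T0 * c^t``; linear: ``T0 * max(eps, 1 - (1-c) t)``;
    logarithmic: ``T0 / log(e + t)``.
    """
    T0, c, t = config.initial_temperature, config.cooling_factor, generation
    floor = 1e-12 * T0  # keep T strictly positive for the acceptance rule
    if kind == "exponential":
        return max(T0 * c**t, floor)
    if kind == "linear":
        return max(T0 * (1.0 - (1.0 - c) * t), floor)
    if kind == "logarithmic":
        return T0 / np.log(np.e + t)
    raise ConfigurationError(f"unknown schedule {kind!r}")


def sa_accept(delta_f: float, temperature: float, rng: np.random.Generator) -> bool:
    """Metropolis rule: always accept improvements; worse moves with
    probability ``exp(delta_f / T)``."""
    if delta_f >= 0:
        return True
    return rng.random() < np.exp(delta_f / temperature)


def sa_step(current: np.ndarray, candidate: np.ndarray, candidate_fitness: float,
            current_fitness: float, temperature: float,
            rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Accept or reject one candidate; returns the surviving (point, fitness)."""
    if not temperature > 0:
        raise ConfigurationError("temperature must be > 0")
    if sa_accept(candidate_fitness - current_fitness, temperature, rng):
        return np.asarray(candidate, dtype=float), float(candidate_fitness)
    return np.asarray(current, dtype=float), float(current_fitness)


class SAOptimizer(Optimizer):
    def __init__(self, config: SAConfig | None = None):
        self.config = config or SAConfig()
        self._current: np.ndarray | None = None       # (n_pop, d) accepted points
        self._current_fitness: np.ndarray | None = None
        self._generation = 0

    def initialize(self, optimizee, n_pop, rng):
        population = super().initialize(optimizee, n_pop, rng)
        spec = optimizee.parameter_spec()
        self._current = self._as_matrix(spec, population)
        self._current_fitness = np.full(n_pop, -np.inf)
        self._generation = 0
        return population

    def step(self, spec, individuals, records, rng):
        candidates = self._as_matrix(spec, individuals)
        cand_fitness = self._scalar_fitness(records)
        T = cooling(self.config.schedule, self._generation, self.config)
        for i in range(candidates.shape[0]):
            self._current[i], self._current_fitness[i] = sa_step(
                self._current[i], candidates[i], cand_fitness[i],
                self._current_fitness[i], T, rng)
        self._generation += 1
        proposals = self._current + rng.normal(
            0.0, self.config.step_scale, size=self._current.shape)
        return self._as_population(spec, proposals, individuals[0].generation + 1)
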
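"""Genetic algorithm: tournament selection, blend crossover, Gaussian
mutation, and an elitist Hall of Fame archive.

The Hall of Fame keeps the best individuals ever evaluated (by scalar
fitness); its best entry is therefore non-decreasing over a run even when
selection noise loses a good solution from the breeding population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ConfigurationError, ContractError
from ..parameters import Individual, ParameterSpec
from ..trajectory import FitnessRecord
from .base import Optimizer

__all__ = ["GAConfig", "HallOfFame", "ga_step", "GAOptimizer"]


@dataclass(frozen=True)
class GAConfig:
    tournament_size: int = 3
    crossover_prob: float = 0.7
    mutation_prob: float = 0.3
    mutation_sigma: float = 1.0
    blend_alpha: float = 0.5
    hof_size: int = 1

    def __post_init__(self):
        if self.tournament_size < 2:
            raise ConfigurationError("tournament_size must be >= 2")
        for p in (self.crossover_prob, self.mutation_prob):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("probabilities must lie in [0, 1]")
        if self.hof_size < 1:
            raise ConfigurationError("hof_size must be >= 1")


class HallOfFame:
    """Fixed-capacity archive of the best (fitness, parameter-vector) pairs."""

    def __init__(self, capacity: int = 1):
        if capacity < 1:
            raise ConfigurationError("Hall of Fame capacity must be >= 1")
        self.capacity = capacity
        self.entries: list[tuple[float, np.ndarray]] = []  # sorted descending

    def update(self, vectors: np.ndarray, fitnesses: np.ndarray) -> None:
        """Merge a generation; keep only strictly better entries on ties so
        the first individual to attain a fitness level is retained."""
        for v, f in zip(vectors, fitnesses):
            f = float(f)
            if len(self.entries) < self.capacity or f > self.entries[-1][0]:
                self.entries.append((f, np.array(v, copy=True)))
                self.entries.sort(key=lambda e: e[0], reverse=True)
                del self.entries[self.capacity:]

    @property
    def best_fitness(self) -> float:
        if not self.entries:
            raise ContractError("empty Hall of Fame")
        return self.entries[0][0]

    @property
    def best_vector(self) -> np.ndarray:
        if not self.entries:
            raise ContractError("empty Hall of Fame")
        return self.entries[0][1]

    def __len__(self) -> int:
        return len(self.entries)


def _tournament(fitnesses: np.ndarray, k: int, rng: np.random.Generator) -> int:
    contenders = rng.integers(0, fitnesses.size, size=k)
    return int(contenders[np.argmax(fitnesses[contenders])])


def ga_step(population: np.ndarray, fitnesses: np.ndarray, config: GAConfig,
            hof: HallOfFame, rng: np.random.Generator) -> np.ndarray:
    """One generation of the GA on a flat (n_pop, d) population matrix.

    Order of operations: the Hall of Fame is updated with the evaluated
    population first, then tournament selection (with replacement) fills the
    mating pool, consecutive pairs undergo blend crossover with probability
    ``crossover_prob``, and each offspring is Gaussian-mutated (every gene,
    scale ``mutation_sigma``) with probability ``mutation_prob``. The
    offspring population has the same size as the input.
    """
    population = np.asarray(population, dtype=float)
    fitnesses = np.asarray(fitnesses, dtype=float)
    n_pop, d = population.shape
    if n_pop < config.tournament_size:
        raise ContractError("population smaller than the tournament size")
    hof.update(population, fitnesses)

    pool = np.stack([
        population[_tournament(fitnesses, config.tournament_size, rng)]
        for _ in range(n_pop)])

    # pairwise blend crossover: child genes sampled in the interval spanned
    # by the parents, extended by blend_alpha on each side
    for i in range(0, n_pop - 1, 2):
        if rng.random() < config.crossover_prob:
            a, b = pool[i].copy(), pool[i + 1].copy()
            u = rng.uniform(-config.blend_alpha, 1 + config.blend_alpha, size=d)
            pool[i] = u * a + (1 - u) * b
            pool[i + 1] = (1 - u) * a + u * b

    for i in range(n_pop):
        if rng.random() < config.mutation_prob:
            pool[i] = pool[i] + rng.normal(0.0, config.mutation_sigma, size=d)
    return pool


class GAOptimizer(Optimizer):
    def __init__(self, config: GAConfig | None = None):
        self.config = config or GAConfig()
        self.hof = HallOfFame(self.config.hof_size)

    def step(self, spec: ParameterSpec, individuals: list[Individual],
             records: list[FitnessRecord], rng: np.random.Generator) -> list[Individual]:
        matrix = self._as_matrix(spec, individuals)
        offspring = ga_step(matrix, self._scalar_fitness(records), self.config,
                            self.hof, rng)
        return self._as_population(spec, offspring, individuals[0].generation + 1)
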
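"""Cross-entropy method: iterated elite refitting of a diagonal Gaussian."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ConfigurationError, ContractError
from .base import Optimizer

__all__ = ["CEConfig", "ce_step", "CEOptimizer"]


@dataclass(frozen=True)
class CEConfig:
    elite_fraction: float = 0.2
    smoothing: float = 0.7          # weight of the fresh elite moments
    variance_floor: float = 1e-12

    def __post_init__(self):
        if not 0.0 < self.elite_fraction <= 1.0:
            raise ConfigurationError("elite_fraction must lie in (0, 1]")
        if not 0.0 < self.smoothing <= 1.0:
            raise ConfigurationError("smoothing must lie in (0, 1]")


def ce_step(population: np.ndarray, fitnesses: np.ndarray, config: CEConfig,
            rng: np.random.Generator,
            prev_mean: np.ndarray | None = None,
            prev_var: np.ndarray | None = None,
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Refit the sampling Gaussian to the elites and draw a new population.

    The top ``elite_fraction`` of the population by fitness is selected
    (at least 2 members), a diagonal Gaussian is fit to it, smoothed toward
    the previous distribution parameters, and a same-size population is
    sampled. A degenerate elite covariance is floored so sampling never
    collapses exactly. Returns ``(mean, var, new_population)``.
    """
    population = np.asarray(population, dtype=float)
    fitnesses = np.asarray(fitnesses, dtype=float)
    n_pop, d = population.shape
    n_elite = max(2, int(round(config.elite_fraction * n_pop)))
    if n_pop < 2:
        raise ContractError("cross-entropy needs at least 2 individuals")
    elites = population[np.argsort(fitnesses)[::-1][:n_elite]]
    mean = elites.mean(axis=0)
    var = elites.var(axis=0)
    if prev_mean is not None:
        s = config.smoothing
        mean = s * mean + (1 - s) * np.asarray(prev_mean, dtype=float)
        var = s * var + (1 - s) * np.asarray(prev_var, dtype=float)
    var = np.maximum(var, config.variance_floor)
    new_population = rng.normal(mean, np.sqrt(var), size=(n_pop, d))
    return mean, var, new_population


class CEOptimizer(Optimizer):
    def __init__(self, config: CEConfig | None = None):
        self.config = config or CEConfig()
        self._mean: np.ndarray | None = None
        self._var: np.ndarray | None = None

    def step(self, spec, individuals, records, rng):
        population = self._as_matrix(spec, individuals)
        self._mean, self._var, new_population = ce_step(
            population, self._scalar_fitness(records), self.config, rng,
            prev_mean=self._mean, prev_var=self._var)
        return self._as_population(spec, new_population,
                                   individuals[0].generation + 1)
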
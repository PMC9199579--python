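"""Evolution strategies: isotropic Gaussian perturbation of a search center
with a stochastic-gradient update weighted by rank-shaped fitness."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ConfigurationError, ContractError
from ..parameters import Individual, ParameterSpec
from .base import Optimizer

__all__ = ["ESConfig", "rank_standardize", "es_step", "ESOptimizer"]


@dataclass(frozen=True)
class ESConfig:
    sigma: float = 0.1
    learning_rate: float = 0.1
    n_offspring: int = 16
    mirrored: bool = True

    def __post_init__(self):
        if not self.sigma > 0:
            raise ConfigurationError("sigma must be > 0")
        if not self.learning_rate > 0:
            raise ConfigurationError("learning_rate must be > 0")
        if self.n_offspring < 2:
            raise ConfigurationError("n_offspring must be >= 2")


def rank_standardize(fitnesses: np.ndarray) -> np.ndarray:
    """Map fitnesses to zero-mean rank utilities in [-0.5, 0.5].

    Ties (e.g. all offspring equal) map to the mean rank and hence to zero
    utility, so a signal-free generation produces no center movement.
    """
    f = np.asarray(fitnesses, dtype=float)
    n = f.size
    order = np.argsort(np.argsort(f, kind="stable"), kind="stable").astype(float)
    # average ranks over ties so equal fitnesses get equal utility
    for v in np.unique(f):
        mask = f == v
        if mask.sum() > 1:
            order[mask] = order[mask].mean()
    return order / (n - 1) - 0.5


def es_step(center: np.ndarray, fitnesses: np.ndarray, noises: np.ndarray,
            config: ESConfig) -> np.ndarray:
    """Move the center along the fitness-shaped average of the noise draws.

    The offspring were ``center + sigma * eps_i`` with recorded ``eps_i``;
    the update is ``center + lr / (n * sigma) * sum_i u_i eps_i`` with
    ``u_i`` the rank-standardized fitnesses.
    """
    center = np.asarray(center, dtype=float)
    noises = np.asarray(noises, dtype=float)
    if noises.shape[0] != np.asarray(fitnesses).size:
        raise ContractError("one noise row per offspring fitness is required")
    u = rank_standardize(fitnesses)
    grad = (u[:, None] * noises).sum(axis=0) / (noises.shape[0] * config.sigma)
    return center + config.learning_rate * grad


class ESOptimizer(Optimizer):
    """Population adapter: each generation is the offspring cloud of a center."""

    def __init__(self, config: ESConfig | None = None):
        self.config = config or ESConfig()
        self._center: np.ndarray | None = None
        self._noises: np.ndarray | None = None

    def _sample(self, spec: ParameterSpec, rng: np.random.Generator,
                generation: int) -> list[Individual]:
        n, d = self.config.n_offspring, self._center.size
        if self.config.mirrored:
            half = rng.normal(size=(n // 2 + n % 2, d))
            eps = np.concatenate([half, -half])[:n]
        else:
            eps = rng.normal(size=(n, d))
        self._noises = eps
        matrix = self._center[None, :] + self.config.sigma * eps
        return self._as_population(spec, matrix, generation)

    def initialize(self, optimizee, n_pop, rng):
        spec = optimizee.parameter_spec()
        self._center = optimizee.create_individual(rng).flatten(spec)
        if n_pop != self.config.n_offspring:
            self.config = ESConfig(
                sigma=self.config.sigma, learning_rate=self.config.learning_rate,
                n_offspring=n_pop, mirrored=self.config.mirrored)
        return self._sample(spec, rng, generation=0)

    def step(self, spec, individuals, records, rng):
        self._center = es_step(self._center, self._scalar_fitness(records),
                               self._noises, self.config)
        return self._sample(spec, rng, individuals[0].generation + 1)
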
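"""Exhaustive grid search over the declared parameter ranges."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ConfigurationError
from ..parameters import Individual, ParameterSpec
from .base import Optimizer

__all__ = ["GridConfig", "grid_generate", "GridOptimizer"]


@dataclass(frozen=True)
class GridConfig:
    resolution: tuple[int, ...] | int = 10
    max_combinations: int = 1_000_000

    def __post_init__(self):
        res = (self.resolution,) if isinstance(self.resolution, int) else self.resolution
        if any(r < 1 for r in res):
            raise ConfigurationError("grid resolution must be >= 1 per parameter")


def grid_generate(spec: ParameterSpec, resolution,
                  max_combinations: int = 1_000_000) -> list[Individual]:
    """Cartesian product of evenly spaced values, endpoints included.

    ``resolution`` is one integer per scalar dimension (a single integer is
    broadcast). The combination count is checked *before* materializing; a
    grid above ``max_combinations`` raises, reporting the count as a power.
    """
    d = spec.dimension
    if isinstance(resolution, (int, np.integer)):
        resolution = [int(resolution)] * d
    resolution = [int(r) for r in resolution]
    if len(resolution) != d:
        raise ConfigurationError(
            f"need one resolution per scalar dimension ({d}), got {len(resolution)}")
    total = 1
    for r in resolution:
        total *= r
    if total > max_combinations:
        base = resolution[0]
        as_power = (f"{base}^{d}" if all(r == base for r in resolution)
                    else "x".join(map(str, resolution)))
        raise ConfigurationError(
            f"grid search would require {as_power} = {total} combinations, "
            f"above the cap of {max_combinations}")
    lo, hi = spec.lower_vector(), spec.upper_vector()
    axes = [np.linspace(lo[i], hi[i], resolution[i]) for i in range(d)]
    mesh = np.meshgrid(*axes, indexing="ij")
    matrix = np.stack([m.ravel() for m in mesh], axis=1)
    return [Individual(values=spec.unflatten(row), id=i, generation=0)
            for i, row in enumerate(matrix)]


class GridOptimizer(Optimizer):
    """One-shot exhaustive evaluation; defines its own population size."""

    def __init__(self, config: GridConfig | None = None):
        self.config = config or GridConfig()
        self._finished = False

    def initialize(self, optimizee, n_pop, rng):
        population = grid_generate(optimizee.parameter_spec(),
                                   self.config.resolution,
                                   self.config.max_combinations)
        return population

    def step(self, spec, individuals, records, rng):
        self._finished = True
        return individuals

    @property
    def finished(self) -> bool:
        return self._finished
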
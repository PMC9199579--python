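"""Closed-form benchmark surfaces for exercising the optimizers.

Both are returned negated (maximization convention): the global optimum is
0 at the origin.
"""

from __future__ import annotations

import numpy as np

from ..errors import ConfigurationError
from ..evaluation import Optimizee
from ..parameters import Individual, ParameterEntry, ParameterSpec

__all__ = ["benchmark_function", "BenchmarkOptimizee"]


def benchmark_function(name: str, x) -> float:
    x = np.asarray(x, dtype=float)
    if name == "sphere":
        return float(-np.sum(x**2))
    if name == "rastrigin":
        return float(-(10.0 * x.size + np.sum(x**2 - 10.0 * np.cos(2 * np.pi * x))))
    raise ConfigurationError(f"unknown benchmark {name!r}; have sphere, rastrigin")


class BenchmarkOptimizee(Optimizee):
    """Sphere/Rastrigin as a framework optimizee (``x`` in [-5, 5]^d)."""

    def __init__(self, name: str = "sphere", dimension: int = 2,
                 low: float = -5.0, high: float = 5.0):
        benchmark_function(name, np.zeros(dimension))  # validate the name
        self.name = name
        self.dimension = dimension
        self.low, self.high = low, high

    def parameter_spec(self) -> ParameterSpec:
        return ParameterSpec((ParameterEntry("x", self.dimension, self.low, self.high),))

    def simulate(self, individual: Individual, rng) -> np.ndarray:
        return np.array([benchmark_function(self.name, individual.values["x"])])
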
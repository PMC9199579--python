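"""Outer-loop optimizer interface.

An optimizer maps one generation's ``(individuals, fitness records)`` to the
next generation's individuals. Populations are handled as flat parameter
matrices internally (row = one individual, layout fixed by the optimizee's
:class:`~metaloop.parameters.ParameterSpec`); the framework re-applies the
bounding function after every step.
"""

from __future__ import annotations

from abc import ABC, abstractmethod

import numpy as np

from ..evaluation import Optimizee
from ..parameters import Individual, ParameterSpec
from ..trajectory import FitnessRecord

__all__ = ["Optimizer"]


class Optimizer(ABC):
    """Population-to-population outer-loop step."""

    def initialize(self, optimizee: Optimizee, n_pop: int,
                   rng: np.random.Generator) -> list[Individual]:
        """First-generation population (uniform within bounds by default)."""
        return [optimizee.create_individual(rng, id=i, generation=0)
                for i in range(n_pop)]

    @abstractmethod
    def step(self, spec: ParameterSpec, individuals: list[Individual],
             records: list[FitnessRecord], rng: np.random.Generator) -> list[Individual]:
        """Produce the next generation from the evaluated current one."""

    @property
    def finished(self) -> bool:
        """True once the optimizer has exhausted its schedule (grid search)."""
        return False

    # -- helpers shared by the concrete optimizers --------------------------

    @staticmethod
    def _as_matrix(spec: ParameterSpec, individuals: list[Individual]) -> np.ndarray:
        return np.stack([ind.flatten(spec) for ind in individuals])

    @staticmethod
    def _as_population(spec: ParameterSpec, matrix: np.ndarray,
                       generation: int) -> list[Individual]:
        return [Individual(values=spec.unflatten(row), id=i, generation=generation)
                for i, row in enumerate(matrix)]

    @staticmethod
    def _scalar_fitness(records: list[FitnessRecord]) -> np.ndarray:
        return np.array([r.scalar_fitness for r in records])
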
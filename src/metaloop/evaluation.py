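"""Inner-loop evaluation of a generation, serial or embarrassingly parallel.

Each individual is evaluated independently with its own RNG whose seed is
derived from ``(experiment seed, generation, individual id)``, so a run is
bit-identical whether it is executed serially or on a process pool. The
HPC back-ends the design abstracts over are hidden behind the small
:class:`Runner` interface; one implementation ships (a local process pool).
"""

from __future__ import annotations

import traceback
from abc import ABC, abstractmethod
from concurrent.futures import ProcessPoolExecutor

import numpy as np

from .errors import ContractError, EvaluationError
from .parameters import Individual, ParameterSpec
from .trajectory import FitnessRecord

__all__ = ["Optimizee", "weighted_fitness", "individual_seed",
           "evaluate_generation", "Runner", "LocalRunner"]


class Optimizee(ABC):
    """Inner-loop contract: parameter spec + one-individual simulation.

    Subclasses define the searchable parameter space via
    :meth:`parameter_spec` and map one individual to a fitness vector in
    :meth:`simulate`. ``create_individual`` and ``bounding_func`` have
    framework-level defaults (uniform sampling within bounds; clipping to
    bounds) that subclasses may override.
    """

    @abstractmethod
    def parameter_spec(self) -> ParameterSpec:
        ...

    @abstractmethod
    def simulate(self, individual: Individual, rng: np.random.Generator) -> np.ndarray:
        """Run one simulation; return the fitness vector (maximization)."""

    def create_individual(self, rng: np.random.Generator, *, id: int = 0,
                          generation: int = 0) -> Individual:
        from .parameters import create_individual
        return create_individual(self.parameter_spec(), rng, id=id, generation=generation)

    def bounding_func(self, individual: Individual) -> Individual:
        from .parameters import apply_bounds
        return apply_bounds(individual, self.parameter_spec())


def weighted_fitness(fitness_vector, weights) -> float:
    """Scalarize a fitness vector by its dot product with the weight tuple."""
    fv = np.asarray(fitness_vector, dtype=float)
    w = np.asarray(weights, dtype=float)
    if fv.shape != w.shape:
        raise ContractError(
            f"fitness vector length {fv.size} != weights length {w.size}")
    return float(fv @ w)


def individual_seed(experiment_seed: int, generation: int, individual_id: int) -> int:
    """Deterministic per-evaluation seed (< 2**31).

    Derived from the triple via :class:`numpy.random.SeedSequence`, so serial
    and parallel evaluation of the same generation see identical streams.
    """
    ss = np.random.SeedSequence((int(experiment_seed), int(generation), int(individual_id)))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _evaluate_one(optimizee: Optimizee, individual: Individual, seed: int):
    try:
        fv = optimizee.simulate(individual, np.random.default_rng(seed))
        return "ok", np.atleast_1d(np.asarray(fv, dtype=float))
    except Exception:
        return "fail", traceback.format_exc()


class Runner(ABC):
    """Where a generation's independent evaluations are executed."""

    @abstractmethod
    def map(self, func, argument_tuples: list[tuple]) -> list:
        ...


class LocalRunner(Runner):
    """Serial (``n_workers == 1``) or local process-pool execution."""

    def __init__(self, n_workers: int = 1):
        if n_workers < 1:
            raise ContractError("n_workers must be >= 1")
        self.n_workers = n_workers

    def map(self, func, argument_tuples):
        if self.n_workers == 1:
            return [func(*args) for args in argument_tuples]
        with ProcessPoolExecutor(max_workers=self.n_workers) as pool:
            return list(pool.map(func, *zip(*argument_tuples)))


def evaluate_generation(
    individuals: list[Individual],
    optimizee: Optimizee,
    *,
    weights=(1.0,),
    experiment_seed: int = 0,
    generation: int = 0,
    n_workers: int = 1,
    runner: Runner | None = None,
) -> list[FitnessRecord]:
    """Evaluate every individual once; one order-aligned record each.

    A raising evaluation is flagged failed and scored ``-inf`` (population
    size is preserved for the population-based optimizers); if *every*
    evaluation fails the run aborts with the first captured traceback.
    """
    runner = runner or LocalRunner(n_workers)
    seeds = [individual_seed(experiment_seed, generation, ind.id) for ind in individuals]
    outcomes = runner.map(_evaluate_one, [
        (optimizee, ind, seed) for ind, seed in zip(individuals, seeds)])

    ok_lengths = [fv.size for status, fv in outcomes if status == "ok"]
    if not ok_lengths:
        first_err = next(msg for status, msg in outcomes if status == "fail")
        raise EvaluationError(
            f"all {len(individuals)} evaluations in generation {generation} failed; "
            f"first failure:\n{first_err}")
    fv_len = ok_lengths[0]

    records = []
    for ind, seed, (status, payload) in zip(individuals, seeds, outcomes):
        if status == "ok":
            fv = payload
            records.append(FitnessRecord(
                individual_id=ind.id, fitness_vector=fv,
                scalar_fitness=weighted_fitness(fv, weights), seed=seed))
        else:
            fv = np.full(fv_len, -np.inf)
            records.append(FitnessRecord(
                individual_id=ind.id, fitness_vector=fv,
                scalar_fitness=-np.inf, seed=seed, failed=True))
    return records
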
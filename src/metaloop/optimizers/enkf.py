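"""Ensemble Kalman inversion with rank-based replacement, for weight fitting.

The update treats the ensemble of parameter vectors as samples of an unknown
and nudges every member toward reproducing a target observation vector using
ensemble covariances only (derivative-free):

    u_j <- u_j + C_ud (C_dd + gamma I)^{-1} (target - g(u_j))

with ``C_ud`` the parameter/prediction cross-covariance and ``C_dd`` the
prediction covariance over the ensemble (population 1/n normalization).
``gamma > 0`` regularizes the solve and plays the role of an inverse learning
rate. A ranking modification replaces the worst members by noisy copies of
the best after each update, widening the explored region.

Parameters are kept in a normalized [0, 1] box derived from fixed declared
bounds (not per-generation min/max), so the mapping is stable across
generations; callers de-normalize before simulating.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from ..errors import ConfigurationError, ContractError
from ..parameters import Individual, ParameterSpec
from ..trajectory import FitnessRecord
from .base import Optimizer

__all__ = ["EnKFConfig", "enkf_update", "rank_replace_perturb",
           "normalize_to_unit", "denormalize_from_unit", "EnKFOptimizer"]


@dataclass(frozen=True)
class EnKFConfig:
    gamma: float = 0.5
    replace_fraction: float = 0.1
    perturb_scale: float = 0.05
    normalize_bounds: tuple[float, float] | None = None

    def __post_init__(self):
        if not self.gamma > 0:
            raise ConfigurationError("gamma must be > 0")
        if not 0.0 <= self.replace_fraction <= 0.5:
            raise ConfigurationError("replace_fraction must lie in [0, 0.5]")
        if self.perturb_scale < 0:
            raise ConfigurationError("perturb_scale must be >= 0")


def normalize_to_unit(x: np.ndarray, bounds: tuple[float, float]) -> np.ndarray:
    low, high = bounds
    return (np.asarray(x, dtype=float) - low) / (high - low)


def denormalize_from_unit(u: np.ndarray, bounds: tuple[float, float]) -> np.ndarray:
    low, high = bounds
    return low + np.asarray(u, dtype=float) * (high - low)


def enkf_update(ensemble: np.ndarray, predictions: np.ndarray,
                target: np.ndarray, gamma: float) -> np.ndarray:
    """One regularized ensemble Kalman update of every member.

    ``ensemble`` is (n_ens, d) parameters (already normalized by the caller),
    ``predictions`` (n_ens, k) the corresponding model outputs, ``target``
    the length-k observation to match. ``(C_dd + gamma I)`` is solved by a
    symmetric positive-definite factorization, which ``gamma > 0``
    guarantees. A zero-spread ensemble is returned unchanged (its
    cross-covariance vanishes).
    """
    ensemble = np.asarray(ensemble, dtype=float)
    predictions = np.asarray(predictions, dtype=float)
    target = np.asarray(target, dtype=float).ravel()
    n_ens = ensemble.shape[0]
    if n_ens < 2:
        raise ContractError("ensemble covariances need at least 2 members")
    if predictions.shape[0] != n_ens:
        raise ContractError("one prediction row per ensemble member is required")
    if predictions.shape[1] != target.size:
        raise ContractError(
            f"prediction length {predictions.shape[1]} != target length {target.size}")
    if not gamma > 0:
        raise ConfigurationError("gamma must be > 0")

    du = ensemble - ensemble.mean(axis=0)
    dg = predictions - predictions.mean(axis=0)
    C_ud = du.T @ dg / n_ens              # (d, k)
    C_dd = dg.T @ dg / n_ens              # (k, k)
    A = C_dd + gamma * np.eye(target.size)
    # solve A X = (target - g(u_j)) for all members at once
    residual = target[None, :] - predictions  # (n_ens, k)
    factor = cho_factor(A, lower=True)
    X = cho_solve(factor, residual.T)          # (k, n_ens)
    return ensemble + (C_ud @ X).T


def rank_replace_perturb(ensemble: np.ndarray, fitnesses: np.ndarray,
                         fraction: float, perturb_scale: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Replace the worst members by noisy copies of the best, rank-to-rank.

    The worst ``floor(fraction * n_ens)`` members become copies of the best
    as many members (best paired with worst, second-best with second-worst,
    ...) plus Gaussian noise of scale ``perturb_scale``. ``fraction = 0`` (or
    too small to replace one member) is the identity.
    """
    ensemble = np.array(ensemble, dtype=float, copy=True)
    fitnesses = np.asarray(fitnesses, dtype=float)
    n_ens = ensemble.shape[0]
    k = int(np.floor(fraction * n_ens))
    if k < 1:
        return ensemble
    order = np.argsort(fitnesses)           # ascending: worst first
    worst, best = order[:k], order[::-1][:k]
    noise = rng.normal(0.0, perturb_scale, size=(k, ensemble.shape[1])) \
        if perturb_scale > 0 else 0.0
    ensemble[worst] = ensemble[best] + noise
    return ensemble


class EnKFOptimizer(Optimizer):
    """Framework adapter around :func:`enkf_update` + :func:`rank_replace_perturb`.

    Convention for the generic two-loop run: the optimizee's fitness vector
    is ``[fitness, observation_0, observation_1, ...]`` — the scalar fitness
    first (weight it with ``(1, 0, ..., 0)``), then the flattened model
    outputs the filter assimilates against ``target``.
    """

    def __init__(self, config: EnKFConfig, target):
        self.config = config
        self.target = np.asarray(target, dtype=float).ravel()

    def step(self, spec: ParameterSpec, individuals: list[Individual],
             records: list[FitnessRecord], rng: np.random.Generator) -> list[Individual]:
        matrix = self._as_matrix(spec, individuals)
        bounds = self.config.normalize_bounds or (
            float(spec.lower_vector().min()), float(spec.upper_vector().max()))
        ensemble = normalize_to_unit(matrix, bounds)
        predictions = np.stack([r.fitness_vector[1:] for r in records])
        fitnesses = self._scalar_fitness(records)
        ensemble = enkf_update(ensemble, predictions, self.target, self.config.gamma)
        ensemble = rank_replace_perturb(
            ensemble, fitnesses, self.config.replace_fraction,
            self.config.perturb_scale, rng)
        new_matrix = denormalize_from_unit(ensemble, bounds)
        return self._as_population(spec, new_matrix, individuals[0].generation + 1)
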
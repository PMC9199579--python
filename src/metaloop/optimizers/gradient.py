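"""Gradient ascent by probe regression, in single-center and multi-individual
(cloud) form.

Neither variant needs analytic gradients: the single-center form estimates
the local gradient by a least-squares fit of probe fitnesses on probe
offsets; the multi form (used for vectorized inner loops that return one
fitness per parameter combination) re-centers each individual on its best
combination, nudges it along the regressed gradient, and regenerates a
shrunken grid cloud around the new center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ConfigurationError, ContractError
from .base import Optimizer

__all__ = ["GDConfig", "gradient_step", "estimate_gradient",
           "multi_gradient_step", "GradientOptimizer", "MultiGradientOptimizer"]


@dataclass(frozen=True)
class GDConfig:
    learning_rate: float = 0.01
    n_probe: int = 8
    probe_scale: float = 0.1
    mode: str = "single"           # "single" | "multi"
    shrink: float = 0.9            # cloud range contraction per step (multi)

    def __post_init__(self):
        if not self.learning_rate >= 0:
            raise ConfigurationError("learning_rate must be >= 0")
        if self.n_probe < 1:
            raise ConfigurationError("n_probe must be >= 1")
        if not self.probe_scale > 0:
            raise ConfigurationError("probe_scale must be > 0")
        if not 0 < self.shrink <= 1:
            raise ConfigurationError("shrink must lie in (0, 1]")
        if self.mode not in ("single", "multi"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")


def estimate_gradient(offsets: np.ndarray, fitnesses: np.ndarray) -> np.ndarray:
    """Least-squares slope of fitness on probe offsets (least-norm when
    there are fewer probes than dimensions)."""
    offsets = np.asarray(offsets, dtype=float)
    y = np.asarray(fitnesses, dtype=float)
    if offsets.shape[0] != y.size:
        raise ContractError("one fitness per probe is required")
    # center both sides: the regression then has no intercept term
    X = offsets - offsets.mean(axis=0)
    g, *_ = np.linalg.lstsq(X, y - y.mean(), rcond=None)
    return g


def gradient_step(center: np.ndarray, probes: np.ndarray,
                  probe_fitnesses: np.ndarray, config: GDConfig) -> np.ndarray:
    """Ascend along the regressed gradient: ``center + lr * g_hat``."""
    center = np.asarray(center, dtype=float)
    g = estimate_gradient(np.asarray(probes, dtype=float) - center, probe_fitnesses)
    return center + config.learning_rate * g


def _cloud_grid(center: np.ndarray, half_range: np.ndarray, n_cloud: int) -> np.ndarray:
    """Near-square grid of ``n_cloud`` combinations spanning center +- range."""
    d = center.size
    per_axis = max(2, int(round(n_cloud ** (1.0 / d))))
    axes = [np.linspace(c - h, c + h, per_axis) for c, h in zip(center, half_range)]
    mesh = np.meshgrid(*axes, indexing="ij")
    cloud = np.stack([m.ravel() for m in mesh], axis=1)
    if cloud.shape[0] > n_cloud:
        cloud = cloud[:n_cloud]
    elif cloud.shape[0] < n_cloud:
        reps = n_cloud - cloud.shape[0]
        cloud = np.concatenate([cloud, np.repeat(center[None, :], reps, axis=0)])
    return cloud


def multi_gradient_step(clouds: np.ndarray, fitness_vectors: np.ndarray,
                        config: GDConfig,
                        half_ranges: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One expand/compress step over per-individual parameter clouds.

    ``clouds`` is (n_ind, n_cloud, d): each individual carries a cloud of
    parameter combinations; ``fitness_vectors`` is (n_ind, n_cloud), one
    fitness per combination (the *expanded* form linking every fitness to
    its parameters). Per individual, the best-fitness combination becomes
    the new center, nudged by ``learning_rate`` along the gradient regressed
    over the cloud, and a new grid cloud spanning the shrunken range is
    emitted (the *compressed* form: parameter combinations only).

    Returns ``(new_clouds, new_half_ranges)``.
    """
    clouds = np.asarray(clouds, dtype=float)
    fv = np.asarray(fitness_vectors, dtype=float)
    if clouds.ndim != 3 or clouds.shape[1] == 0:
        raise ContractError("each individual needs a nonempty cloud")
    if fv.shape != clouds.shape[:2]:
        raise ContractError("one fitness per cloud combination is required")
    n_ind, n_cloud, d = clouds.shape
    half_ranges = np.asarray(half_ranges, dtype=float)

    new_clouds = np.empty_like(clouds)
    new_ranges = half_ranges * config.shrink
    for i in range(n_ind):
        best = clouds[i, np.argmax(fv[i])]
        g = estimate_gradient(clouds[i] - clouds[i].mean(axis=0), fv[i])
        center = best + config.learning_rate * g
        new_clouds[i] = _cloud_grid(center, new_ranges[i], n_cloud)
    return new_clouds, new_ranges


class GradientOptimizer(Optimizer):
    """Single-center probe-regression gradient ascent.

    The generation population is the probe cloud around the current center
    (the center itself is evaluated as individual 0).
    """

    def __init__(self, config: GDConfig | None = None):
        self.config = config or GDConfig()
        self._center: np.ndarray | None = None

    def _probes(self, spec, rng, generation):
        n = self.config.n_probe
        matrix = np.concatenate([
            self._center[None, :],
            self._center[None, :] + rng.normal(
                0.0, self.config.probe_scale, size=(n - 1, self._center.size)),
        ]) if n > 1 else self._center[None, :]
        return self._as_population(spec, matrix, generation)

    def initialize(self, optimizee, n_pop, rng):
        spec = optimizee.parameter_spec()
        self._center = optimizee.create_individual(rng).flatten(spec)
        if n_pop != self.config.n_probe:
            self.config = GDConfig(
                learning_rate=self.config.learning_rate, n_probe=n_pop,
                probe_scale=self.config.probe_scale, mode=self.config.mode,
                shrink=self.config.shrink)
        return self._probes(spec, rng, generation=0)

    def step(self, spec, individuals, records, rng):
        probes = self._as_matrix(spec, individuals)
        self._center = gradient_step(
            self._center, probes, self._scalar_fitness(records), self.config)
        return self._probes(spec, rng, individuals[0].generation + 1)


class MultiGradientOptimizer(Optimizer):
    """Cloud-per-individual gradient ascent for vectorized inner loops.

    The framework population of size ``n_individuals * n_cloud`` is the
    concatenation of every individual's cloud; fitness records are expanded
    back to (individual, combination) form before each step.
    """

    def __init__(self, config: GDConfig | None = None, *, n_individuals: int = 4,
                 n_cloud: int = 64):
        self.config = config or GDConfig(mode="multi")
        self.n_individuals = n_individuals
        self.n_cloud = n_cloud
        self._half_ranges: np.ndarray | None = None

    def initialize(self, optimizee, n_pop, rng):
        spec = optimizee.parameter_spec()
        if n_pop != self.n_individuals * self.n_cloud:
            raise ContractError(
                f"population size must be n_individuals * n_cloud = "
                f"{self.n_individuals * self.n_cloud}, got {n_pop}")
        lo, hi = spec.lower_vector(), spec.upper_vector()
        centers = np.stack([
            optimizee.create_individual(rng).flatten(spec)
            for _ in range(self.n_individuals)])
        self._half_ranges = np.tile((hi - lo) / 2.0, (self.n_individuals, 1))
        clouds = np.stack([
            _cloud_grid(c, h, self.n_cloud)
            for c, h in zip(centers, self._half_ranges)])
        return self._as_population(spec, clouds.reshape(-1, centers.shape[1]), 0)

    def step(self, spec, individuals, records, rng):
        d = spec.dimension
        clouds = self._as_matrix(spec, individuals).reshape(
            self.n_individuals, self.n_cloud, d)
        fv = self._scalar_fitness(records).reshape(self.n_individuals, self.n_cloud)
        new_clouds, self._half_ranges = multi_gradient_step(
            clouds, fv, self.config, self._half_ranges)
        return self._as_population(
            spec, new_clouds.reshape(-1, d), individuals[0].generation + 1)
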
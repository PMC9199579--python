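"""Whole-brain surrogate: coupled noisy limit-cycle oscillators on a
structural connectivity (SC) matrix, and the multi-gradient fit of the
(coupling, speed) pair maximizing the functional-structural correlation.

Each region is a planar limit-cycle oscillator (radius sqrt(a), angular
velocity ~1 rad per time unit, slightly heterogeneous across regions)
receiving delayed input ``coupling * sum_j SC_ij x_j(t - d_ij)`` where the
delay is an index-distance proxy divided by the conduction speed. All
parameter combinations in a batch share one noise realization (common
random numbers), so fitness comparisons across combinations are smooth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ContractError, MetaloopError
from ..fitness import fc_sc_fitness
from ..optimizers.gradient import GDConfig, multi_gradient_step, _cloud_grid

__all__ = ["modular_sc", "oscillator_network", "oscillator_batch",
           "fc_fitness_batch", "fit_fc", "FCFitResult",
           "COUPLING_RANGE", "SPEED_RANGE"]

COUPLING_RANGE = (0.0, 1.0)
SPEED_RANGE = (0.5, 5.0)
_LIMIT_CYCLE_A = 0.25
_NOISE_SIGMA = 0.05
_DIVERGENCE_LIMIT = 50.0


def modular_sc(n_regions: int = 10, n_modules: int = 2,
               rng: np.random.Generator | None = None) -> np.ndarray:
    """Block-modular SC: strong within-module weights, weak between."""
    rng = rng or np.random.default_rng(0)
    module = np.arange(n_regions) * n_modules // n_regions
    same = module[:, None] == module[None, :]
    SC = np.where(same, rng.uniform(0.7, 1.0, (n_regions, n_regions)),
                  rng.uniform(0.02, 0.15, (n_regions, n_regions)))
    SC = (SC + SC.T) / 2.0
    np.fill_diagonal(SC, 0.0)
    return SC


def oscillator_batch(SC: np.ndarray, coupling: np.ndarray, speed: np.ndarray,
                     steps: int = 600, dt: float = 0.1,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Simulate B parameter combinations at once; returns (B, n, steps).

    ``coupling`` and ``speed`` are length-B vectors. The same noise sequence
    drives every combination.
    """
    SC = np.asarray(SC, dtype=float)
    n = SC.shape[0]
    if SC.shape != (n, n):
        raise ContractError("SC must be square")
    coupling = np.atleast_1d(np.asarray(coupling, dtype=float))
    speed = np.atleast_1d(np.asarray(speed, dtype=float))
    B = coupling.size
    rng = rng or np.random.default_rng(0)

    dist = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :]).astype(float)
    delays = np.rint(dist[None, :, :] / (speed[:, None, None] * dt)).astype(int)
    delays = np.maximum(delays, 1)
    L = delays.max() + 1

    omega = 1.0 + 0.2 * np.linspace(-1, 1, n)   # heterogeneous frequencies
    x = np.tile(0.1 * np.cos(np.linspace(0, 2 * np.pi, n, endpoint=False)), (B, 1))
    y = np.tile(0.1 * np.sin(np.linspace(0, 2 * np.pi, n, endpoint=False)), (B, 1))
    hist = np.zeros((L, B, n))
    hist[:] = x[None, :, :]

    b_idx = np.arange(B)[:, None, None]
    j_idx = np.arange(n)[None, None, :]
    out = np.empty((B, n, steps))
    sq = np.sqrt(dt)

    for t in range(steps):
        p = t % L
        rows = (p - delays) % L
        x_del = hist[rows, b_idx, j_idx]                    # (B, n, n)
        coupled = coupling[:, None] * (SC[None, :, :] * x_del).sum(axis=2)
        r2 = x * x + y * y
        noise = _NOISE_SIGMA * rng.normal(size=n)           # shared across B
        dx = ((_LIMIT_CYCLE_A - r2) * x - omega * y + coupled) * dt + noise * sq
        dy = ((_LIMIT_CYCLE_A - r2) * y + omega * x) * dt
        x = x + dx
        y = y + dy
        if np.abs(x).max() > _DIVERGENCE_LIMIT:
            raise MetaloopError("oscillator network diverged "
                                f"(|x| > {_DIVERGENCE_LIMIT} at step {t})")
        hist[(p + 1) % L] = x
        out[:, :, t] = x
    return out


def oscillator_network(SC: np.ndarray, coupling: float, speed: float,
                       steps: int = 600, dt: float = 0.1,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Region time series (n_regions, steps) for one parameter pair."""
    return oscillator_batch(SC, [coupling], [speed], steps, dt, rng)[0]


def fc_fitness_batch(SC: np.ndarray, params: np.ndarray, *, steps: int = 600,
                     dt: float = 0.1, noise_seed: int = 12345,
                     discard_fraction: float = 0.2) -> np.ndarray:
    """Functional-structural fitness for a (B, 2) array of (coupling, speed).

    The initial transient is discarded before computing functional
    connectivity. A fixed ``noise_seed`` keeps the fitness landscape
    deterministic so optimization runs and grid oracles are comparable.
    """
    params = np.atleast_2d(np.asarray(params, dtype=float))
    series = oscillator_batch(SC, params[:, 0], params[:, 1], steps, dt,
                              np.random.default_rng(noise_seed))
    start = int(discard_fraction * series.shape[2])
    return np.array([fc_sc_fitness(SC, s[:, start:]) for s in series])


@dataclass
class FCFitResult:
    best_params: np.ndarray            # (coupling, speed)
    best_fitness: float
    best_history: np.ndarray           # best fitness per generation
    expanded_per_generation: int       # individuals x cloud size


def fit_fc(SC: np.ndarray, *, seed: int = 0, n_individuals: int = 4,
           n_cloud: int = 64, learning_rate: float = 0.01,
           generations: int = 30, steps: int = 600, dt: float = 0.1,
           noise_seed: int = 12345) -> FCFitResult:
    """Multi-gradient ascent on (coupling, speed) over per-individual clouds.

    Every generation expands ``n_individuals * n_cloud`` parameter
    combinations, evaluates them all in one vectorized simulation batch,
    re-centers each individual on its best combination (nudged along the
    regressed gradient) and regenerates a shrunken grid cloud around it.
    """
    SC = np.asarray(SC, dtype=float)
    rng = np.random.default_rng(seed)
    lo = np.array([COUPLING_RANGE[0], SPEED_RANGE[0]])
    hi = np.array([COUPLING_RANGE[1], SPEED_RANGE[1]])
    config = GDConfig(learning_rate=learning_rate, mode="multi")

    centers = rng.uniform(lo, hi, size=(n_individuals, 2))
    half = np.tile((hi - lo) / 2.0, (n_individuals, 1))
    clouds = np.stack([_cloud_grid(c, h, n_cloud) for c, h in zip(centers, half)])

    best_params, best_fitness, history = None, -np.inf, []
    for _ in range(generations):
        flat = np.clip(clouds.reshape(-1, 2), lo, hi)
        fitnesses = fc_fitness_batch(SC, flat, steps=steps, dt=dt,
                                     noise_seed=noise_seed)
        fv = fitnesses.reshape(n_individuals, n_cloud)
        k = int(np.argmax(fitnesses))
        if fitnesses[k] > best_fitness:
            best_fitness = float(fitnesses[k])
            best_params = flat[k].copy()
        history.append(best_fitness)
        clouds, half = multi_gradient_step(
            flat.reshape(n_individuals, n_cloud, 2), fv, config, half)
    return FCFitResult(best_params=best_params, best_fitness=best_fitness,
                       best_history=np.array(history),
                       expanded_per_generation=n_individuals * n_cloud)
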
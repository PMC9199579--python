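"""Desk-scale single-cell fitting testbed.

A deterministic adaptive leaky integrate-and-fire cell stands in for a
morphologically detailed neuron: it has a leak conductance and reversal, a
capacitance, a spike threshold with reset, and a spike-triggered adaptation
current. Spikes are pasted into the voltage trace as fixed-height
deflections so threshold-based spike-feature fitness terms have support.

The fitting pipeline plants known parameters, generates reference traces for
a set of current-clamp stimuli, and asks the genetic algorithm to recover
selected free parameters from the trace fitness alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ..errors import ConfigurationError, ContractError
from ..fitness import VoltageTrace, spike_feature_fitness, trace_square_loss
from ..optimizers.ga import GAConfig, HallOfFame, ga_step
from ..parameters import Individual
from ..trajectory import FitnessRecord, Trajectory

__all__ = ["ToyCellParams", "StimulusClamp", "toy_cell_trace",
           "toy_cell_traces_batch", "fit_cell", "CellFitResult"]


@dataclass(frozen=True)
class ToyCellParams:
    """Adaptive LIF cell constants.

    Units: conductance uS, potentials mV, capacitance nF, currents nA,
    times ms — so tau_m = capacitance / g_leak is in ms (10 ms by default).
    """

    g_leak: float = 0.05          # uS
    e_leak: float = -70.0         # mV
    capacitance: float = 0.5      # nF
    threshold: float = -50.0      # mV
    reset: float = -65.0          # mV
    adapt_increment: float = 0.02  # nA added to the adaptation current per spike
    adapt_tau: float = 100.0      # ms
    spike_height: float = 20.0    # mV value pasted at spike samples

    def __post_init__(self):
        if not (self.g_leak > 0 and self.capacitance > 0 and self.adapt_tau > 0):
            raise ConfigurationError(
                "conductance, capacitance and time constants must be positive")

    @property
    def tau_m(self) -> float:
        return self.capacitance / self.g_leak


@dataclass(frozen=True)
class StimulusClamp:
    """Square current-clamp stimulus: onset delay, duration, amplitude (nA)."""

    delay: float = 50.0
    duration: float = 200.0
    amplitude: float = 1.2

    def __post_init__(self):
        if self.delay < 0 or self.duration < 0:
            raise ConfigurationError("clamp delay and duration must be >= 0")

    def current(self, times: np.ndarray) -> np.ndarray:
        return np.where((times >= self.delay) & (times < self.delay + self.duration),
                        self.amplitude, 0.0)


def toy_cell_traces_batch(g_leak: np.ndarray, e_leak: np.ndarray,
                          base: ToyCellParams, clamp: StimulusClamp,
                          duration: float, dt: float) -> np.ndarray:
    """Integrate B cells that differ in (g_leak, e_leak); returns (B, T+1) mV.

    Euler integration of ``C dV/dt = -g_leak (V - e_leak) - w + I`` with the
    adaptation current ``w`` decaying with ``adapt_tau`` and incremented at
    each spike; at threshold the sample is pasted to ``spike_height`` and V
    resets.
    """
    if dt > min(base.tau_m, base.adapt_tau):
        warnings.warn("integration step exceeds the fastest time constant")
        raise ConfigurationError(
            f"dt={dt} ms is unstable for tau_m={base.tau_m} ms")
    g = np.asarray(g_leak, dtype=float)
    E = np.asarray(e_leak, dtype=float)
    B = g.size
    n_steps = int(round(duration / dt))
    times = np.arange(n_steps + 1) * dt
    I = clamp.current(times)
    V = E.copy()
    w = np.zeros(B)
    out = np.empty((B, n_steps + 1))
    out[:, 0] = V
    for t in range(1, n_steps + 1):
        dV = dt * (-g * (V - E) - w + I[t - 1]) / base.capacitance
        V = V + dV
        w = w * (1.0 - dt / base.adapt_tau)
        spiking = V >= base.threshold
        out[:, t] = np.where(spiking, base.spike_height, V)
        V = np.where(spiking, base.reset, V)
        w = np.where(spiking, w + base.adapt_increment, w)
    return out


def toy_cell_trace(params: ToyCellParams, clamp: StimulusClamp,
                   duration: float = 400.0, dt: float = 0.1) -> VoltageTrace:
    """Deterministic voltage response of one cell to one current clamp."""
    samples = toy_cell_traces_batch(
        np.array([params.g_leak]), np.array([params.e_leak]),
        params, clamp, duration, dt)[0]
    return VoltageTrace(samples=samples, dt=dt)


# passive-parameter recovery uses subthreshold steps (rheobase is 1.0 nA at
# the default constants): the square trace loss is then smooth in the leak
# parameters, whereas spike-pasted traces make it rugged under misalignment
DEFAULT_CLAMPS = (StimulusClamp(delay=50.0, duration=200.0, amplitude=0.6),
                  StimulusClamp(delay=50.0, duration=200.0, amplitude=0.85))

FREE_BOUNDS = {"g_leak": (0.02, 0.1), "e_leak": (-80.0, -60.0)}


@dataclass
class CellFitResult:
    trajectory: Trajectory
    hof: HallOfFame
    recovered: dict[str, float]
    truth: dict[str, float]

    @property
    def relative_errors(self) -> dict[str, float]:
        return {k: abs(self.recovered[k] - self.truth[k]) / abs(self.truth[k])
                for k in self.recovered}


def _fitness_matrix(pop: np.ndarray, reference: list[VoltageTrace],
                    base: ToyCellParams, clamps, duration, dt,
                    mode: str, spike_sigma: float) -> np.ndarray:
    """(B, n_objectives) fitness for a (B, 2) population of (g_leak, e_leak)."""
    B = pop.shape[0]
    cols = []
    for clamp, ref in zip(clamps, reference):
        traces = toy_cell_traces_batch(pop[:, 0], pop[:, 1], base, clamp,
                                       duration, dt)
        if mode == "square":
            cols.append(np.array([
                trace_square_loss(ref, VoltageTrace(traces[b], dt))
                for b in range(B)]))
        else:
            pairs = [spike_feature_fitness(ref, VoltageTrace(traces[b], dt),
                                           spike_sigma) for b in range(B)]
            cols.append(np.array([-L for L, _ in pairs]))
            cols.append(np.array([-abs(S) for _, S in pairs]))
    return np.stack(cols, axis=1)


def fit_cell(
    reference_params: ToyCellParams | None = None,
    clamps=DEFAULT_CLAMPS,
    *,
    seed: int = 0,
    population: int = 100,
    generations: int = 200,
    ga_config: GAConfig | None = None,
    duration: float = 300.0,
    dt: float = 0.2,
    fitness: str = "square",        # "square" (trace loss) | "features" (L,S terms)
    spike_sigma: float = -20.0,
    record_trajectory: bool = False,
) -> CellFitResult:
    """Recover planted (g_leak, e_leak) from reference traces with the GA.

    The reference traces are generated internally from ``reference_params``
    for every clamp; the per-clamp fitness is the negative square trace loss
    (or the negated spike-feature terms), summed into the scalar fitness the
    GA maximizes. Parameters are clipped to their declared bounds after
    every step.
    """
    truth_params = reference_params or ToyCellParams()
    clamps = tuple(clamps)
    reference = [toy_cell_trace(truth_params, c, duration, dt) for c in clamps]
    lo = np.array([FREE_BOUNDS["g_leak"][0], FREE_BOUNDS["e_leak"][0]])
    hi = np.array([FREE_BOUNDS["g_leak"][1], FREE_BOUNDS["e_leak"][1]])
    if not (lo[0] <= truth_params.g_leak <= hi[0]
            and lo[1] <= truth_params.e_leak <= hi[1]):
        raise ContractError("planted parameters must lie inside the search bounds")

    rng = np.random.default_rng(seed)
    # GA breeding runs in [0,1]-normalized coordinates so a single mutation
    # sigma suits both parameters despite their very different magnitudes
    config = ga_config or GAConfig(mutation_sigma=0.05, hof_size=1)

    pop = rng.uniform(lo, hi, size=(population, 2))
    hof = HallOfFame(config.hof_size)
    traj = Trajectory(config={"optimizee": "toy-cell", "optimizer": "genetic-algorithm",
                              "n_pop": population}, seed=seed)

    for gen in range(generations):
        fm = _fitness_matrix(pop, reference, truth_params, clamps, duration,
                             dt, fitness, spike_sigma)
        fitnesses = fm.sum(axis=1)
        if record_trajectory:
            individuals = [Individual(values={"g_leak": np.array([p[0]]),
                                              "e_leak": np.array([p[1]])},
                                      id=i, generation=gen)
                           for i, p in enumerate(pop)]
            records = [FitnessRecord(individual_id=i, fitness_vector=fm[i],
                                     scalar_fitness=float(f), seed=seed)
                       for i, f in enumerate(fitnesses)]
            traj.append(individuals, records)
        hof.update(pop, fitnesses)
        pop_n = (pop - lo) / (hi - lo)
        pop_n = ga_step(pop_n, fitnesses, config, HallOfFame(1), rng)
        pop = np.clip(lo + pop_n * (hi - lo), lo, hi)

    best = hof.best_vector
    return CellFitResult(
        trajectory=traj, hof=hof,
        recovered={"g_leak": float(best[0]), "e_leak": float(best[1])},
        truth={"g_leak": truth_params.g_leak, "e_leak": truth_params.e_leak})
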
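"""Fitness and loss functions used by the testbed optimizees.

All functions follow the framework's maximization convention: quantities that
are naturally losses are returned negated (or transformed, e.g. ``1 - MSE``)
so that every optimizer can treat larger as better.

Contents:

* :func:`softmax`, :func:`mse_fitness` — spiking-reservoir digit classification
  readout (softmax over output-cluster firing rates, fitness ``1 - MSE``
  against one-hot labels).
* :func:`trace_square_loss`, :func:`spike_feature_fitness`,
  :func:`stimulus_fitness_vector` — electrophysiological trace fitting
  (negative square loss; mean-potential and spike-selective feature terms;
  interleaved multi-stimulus fitness vector).
* :func:`colony_fitness` — ant-colony foraging score over an event log of
  per-ant actions with fixed per-event rewards/costs.
* :func:`pearson`, :func:`fc_sc_fitness` — functional-connectivity /
  structural-connectivity correlation for whole-brain surrogate fitting.
* :func:`mc_fitness` — mountain-car episode score (maximum position reached).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError

__all__ = [
    "VoltageTrace",
    "ColonyCosts",
    "EventLog",
    "softmax",
    "mse_fitness",
    "trace_square_loss",
    "spike_feature_fitness",
    "stimulus_fitness_vector",
    "colony_fitness",
    "pearson",
    "fc_sc_fitness",
    "mc_fitness",
]


# ---------------------------------------------------------------------------
# domain containers


@dataclass(frozen=True)
class VoltageTrace:
    """Sampled membrane potential: ``samples`` in mV at interval ``dt`` ms."""

    samples: np.ndarray
    dt: float

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ContractError("a voltage trace needs at least 2 samples")
        if not self.dt > 0:
            raise ContractError("sampling interval dt must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.dt

    def to_csv(self, path) -> None:
        pd.DataFrame({"t_ms": self.times, "mV": self.samples}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "VoltageTrace":
        df = pd.read_csv(path)
        t = df["t_ms"].to_numpy()
        return cls(samples=df["mV"].to_numpy(), dt=float(t[1] - t[0]))


@dataclass(frozen=True)
class ColonyCosts:
    """Per-event rewards (positive) and costs (negative) for colony foraging.

    The movement-related costs deliberately dominate exploration so that
    colonies are pushed to retrieve food rather than wander; the nest-return
    reward is large because it is the rare terminal event of a successful
    foraging trip.
    """

    rotation: float = -0.02
    pheromone_drop: float = -0.05
    movement: float = -0.25
    resting: float = -0.5
    nest_return: float = 220.0
    food_touch: float = 1.5

    def value(self, kind: str) -> float:
        try:
            return getattr(self, kind)
        except AttributeError:
            raise ContractError(f"unknown event kind {kind!r}") from None

    @property
    def kinds(self) -> tuple[str, ...]:
        return ("rotation", "pheromone_drop", "movement", "resting", "nest_return", "food_touch")


@dataclass
class EventLog:
    """Timestamped colony actions: ``(time step, ant id, event kind)``."""

    events: list[tuple[int, int, str]] = field(default_factory=list)

    def append(self, t: int, ant: int, kind: str) -> None:
        self.events.append((int(t), int(ant), kind))

    def __add__(self, other: "EventLog") -> "EventLog":
        return EventLog(events=list(self.events) + list(other.events))

    def __len__(self) -> int:
        return len(self.events)

    @classmethod
    def from_csv(cls, path) -> "EventLog":
        """Read ``t,ant_id,event`` rows so external agent worlds can be scored."""
        df = pd.read_csv(path)
        return cls(events=[(int(t), int(a), str(e)) for t, a, e in
                           zip(df["t"], df["ant_id"], df["event"])])

    def to_csv(self, path) -> None:
        pd.DataFrame(self.events, columns=["t", "ant_id", "event"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# classification readout


def softmax(x) -> np.ndarray:
    """Numerically safe softmax (shift-invariant: the max is subtracted)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ContractError("softmax of an empty vector")
    z = np.exp(x - np.max(x))
    return z / z.sum()


def mse_fitness(label_onehot, prediction) -> float:
    """Classification fitness ``f = 1 - L`` with L the mean squared error.

    ``label_onehot`` is the one-hot encoded class label; ``prediction`` the
    (softmax) model output. Perfect prediction gives 1.
    """
    y = np.asarray(label_onehot, dtype=float)
    yhat = np.asarray(prediction, dtype=float)
    if y.shape != yhat.shape:
        raise ContractError(f"label shape {y.shape} != prediction shape {yhat.shape}")
    return float(1.0 - np.mean((y - yhat) ** 2))


# ---------------------------------------------------------------------------
# trace fitting


def _check_aligned(ref: VoltageTrace, sim: VoltageTrace) -> None:
    if ref.samples.size != sim.samples.size:
        raise ContractError(
            f"trace lengths differ ({ref.samples.size} vs {sim.samples.size})"
        )
    if ref.dt != sim.dt:
        raise ContractError(f"sampling intervals differ ({ref.dt} vs {sim.dt})")


def trace_square_loss(ref: VoltageTrace, sim: VoltageTrace, *,
                      normalization: str = "printed") -> float:
    """Negative square loss between a reference and a simulated trace.

    With samples indexed ``t = 0..T`` the returned value is

        -(1/T^2) * sum_t [U_ref(t) - U_sim(t)]^2

    i.e. the ``1/T^2`` prefactor is used verbatim (``normalization="printed"``,
    the default). ``normalization="samples"`` switches to the conventional
    per-sample mean ``1/(T+1)``. The sign is negative so that optimizers
    maximizing fitness drive the traces together.
    """
    _check_aligned(ref, sim)
    n = ref.samples.size  # n = T + 1 samples
    sq = float(np.sum((ref.samples - sim.samples) ** 2))
    if normalization == "printed":
        return -sq / (n - 1) ** 2
    if normalization == "samples":
        return -sq / n
    raise ContractError(f"unknown normalization {normalization!r}")


def spike_feature_fitness(ref: VoltageTrace, sim: VoltageTrace,
                          threshold: float) -> tuple[float, float]:
    """Feature-based trace comparison ``(L, S)``.

    ``L`` is the absolute difference of the temporal mean potentials; ``S``
    is the temporal average of ``U_ref - U_sim`` restricted to samples where
    the reference exceeds ``threshold`` (a spike-selecting potential in mV),
    zero when no reference sample crosses it. ``L >= 0``; ``S`` can take any
    sign (it measures how much spike-region depolarization the simulation is
    missing or overshooting).
    """
    _check_aligned(ref, sim)
    L = float(abs(ref.samples.mean() - sim.samples.mean()))
    mask = ref.samples > threshold
    S = float((ref.samples[mask] - sim.samples[mask]).mean()) if mask.any() else 0.0
    return L, S


def stimulus_fitness_vector(per_stimulus: list[tuple[float, float]]) -> np.ndarray:
    """Interleave per-stimulus ``(L, S)`` pairs into one fitness vector.

    Layout: ``(L_0, S_0, L_1, S_1, ...)`` — one ``(L, S)`` block per stimulus,
    ready for scalarization with a weight tuple by the framework.
    """
    if len(per_stimulus) == 0:
        raise ContractError("at least one stimulus is required")
    return np.array([v for pair in per_stimulus for v in pair], dtype=float)


# ---------------------------------------------------------------------------
# colony foraging


def colony_fitness(log: EventLog, costs: ColonyCosts | None = None) -> float:
    """Sum the signed per-event constants over a colony event log.

    Rewards (nest returns, food touches) add; action costs (movement,
    rotation, pheromone drops, resting) subtract via their negative constants.
    Additive over log concatenation.
    """
    costs = costs or ColonyCosts()
    return float(sum(costs.value(kind) for _, _, kind in log.events))


# ---------------------------------------------------------------------------
# connectivity correlation


def pearson(x, y) -> float:
    """Pearson product-moment correlation coefficient of two vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ContractError("pearson needs two equal-length 1-d vectors")
    if x.size < 2:
        raise ContractError("pearson needs at least 2 samples")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ContractError("pearson undefined for a zero-variance input")
    return float(np.corrcoef(x, y)[0, 1])


def fc_sc_fitness(SC: np.ndarray, series: np.ndarray) -> float:
    """Correlation between simulated functional and structural connectivity.

    Step 1: the functional connectivity (FC) matrix is the pairwise Pearson
    correlation of the per-region time series. Step 2: the structural
    connectivity (SC) weights are normalized by their maximum entry, and the
    fitness is the Pearson correlation between the upper-triangular
    off-diagonal entries of FC and of the normalized SC (the FC diagonal is
    identically 1 and carries no information).
    """
    SC = np.asarray(SC, dtype=float)
    series = np.asarray(series, dtype=float)
    n = SC.shape[0]
    if SC.shape != (n, n):
        raise ContractError("SC must be square")
    if series.shape[0] != n:
        raise ContractError(f"series has {series.shape[0]} regions, SC has {n}")
    if np.any(np.std(series, axis=1) == 0):
        raise ContractError("a region time series has zero variance")
    FC = np.corrcoef(series)
    SC_norm = SC / SC.max()
    iu = np.triu_indices(n, k=1)
    return pearson(FC[iu], SC_norm[iu])


# ---------------------------------------------------------------------------
# mountain car


def mc_fitness(positions) -> float:
    """Maximum horizontal position reached during an episode."""
    positions = np.asarray(positions, dtype=float)
    if positions.size == 0:
        raise ContractError("empty position trace")
    return float(positions.max())
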
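"""Network containers for the LIF simulator.

A :class:`NetworkSpec` is a plain synapse table (pre, post, weight, integer
delay in steps) plus neuron flags and labeled populations; builders produce
it deterministically so a flat weight vector always maps to the same
synapses. Synaptic weights are dimensionless; the simulator converts them to
membrane-potential jumps via ``weight_scale`` (mV per weight unit).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..errors import ConfigurationError, ContractError

__all__ = ["LIFParams", "NetworkSpec", "SpikeRecord"]


@dataclass(frozen=True)
class LIFParams:
    """Leaky integrate-and-fire point-neuron constants.

    Defaults: 10 ms membrane time constant, rest/reset at -70 mV, threshold
    -55 mV, 2 ms absolute refractory period, 10 MOhm membrane resistance.
    """

    tau_m: float = 10.0        # ms
    v_rest: float = -70.0      # mV (also the reset potential)
    v_reset: float = -70.0     # mV
    v_threshold: float = -55.0  # mV
    t_refractory: float = 2.0  # ms
    resistance: float = 10.0   # MOhm

    def __post_init__(self):
        if not (self.tau_m > 0 and self.t_refractory >= 0 and self.resistance > 0):
            raise ConfigurationError("time constants and resistance must be positive")
        if not self.v_threshold > self.v_reset:
            raise ConfigurationError("threshold must exceed the reset potential")


@dataclass
class NetworkSpec:
    """Neurons + synapse table + labeled populations."""

    n_neurons: int
    pre: np.ndarray
    post: np.ndarray
    weight: np.ndarray
    delay: np.ndarray                      # integer steps, >= 1
    excitatory: np.ndarray | None = None   # bool per neuron
    populations: dict[str, np.ndarray] = field(default_factory=dict)
    spike_sources: np.ndarray | None = None  # neuron ids driven externally
    weight_scale: float = 0.1              # mV of jump per weight unit
    params: LIFParams = field(default_factory=LIFParams)
    synapse_groups: dict[str, slice] = field(default_factory=dict)
    """Named contiguous blocks of the synapse table (builder-documented
    ordering), so flat weight vectors map stably onto synapses."""

    def __post_init__(self):
        self.pre = np.asarray(self.pre, dtype=int)
        self.post = np.asarray(self.post, dtype=int)
        self.weight = np.asarray(self.weight, dtype=float)
        self.delay = np.asarray(self.delay, dtype=int)
        n_syn = self.pre.size
        if not (self.post.size == self.weight.size == self.delay.size == n_syn):
            raise ContractError("synapse table columns must have equal length")
        if n_syn and self.delay.min() < 1:
            raise ContractError("synaptic delays must be >= 1 step")
        if n_syn and (self.pre.max() >= self.n_neurons or self.post.max() >= self.n_neurons):
            raise ContractError("synapse endpoint outside the neuron range")
        if self.excitatory is None:
            self.excitatory = np.ones(self.n_neurons, dtype=bool)

    @property
    def n_synapses(self) -> int:
        return self.pre.size

    def population(self, label: str) -> np.ndarray:
        try:
            return self.populations[label]
        except KeyError:
            raise ContractError(
                f"no population {label!r}; have {sorted(self.populations)}") from None

    def with_weights(self, weights: np.ndarray) -> "NetworkSpec":
        """Same topology with a replacement weight vector (synapse order)."""
        weights = np.asarray(weights, dtype=float)
        if weights.size != self.n_synapses:
            raise ContractError(
                f"expected {self.n_synapses} weights, got {weights.size}")
        return NetworkSpec(
            n_neurons=self.n_neurons, pre=self.pre, post=self.post,
            weight=weights, delay=self.delay, excitatory=self.excitatory,
            populations=self.populations, spike_sources=self.spike_sources,
            weight_scale=self.weight_scale, params=self.params,
            synapse_groups=self.synapse_groups)

    # -- CSV edge-list exchange (external-optimizee compatible) -------------

    def to_csv(self, path) -> None:
        pd.DataFrame({"pre": self.pre, "post": self.post,
                      "weight": self.weight, "delay": self.delay}
                     ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, n_neurons: int | None = None, **kwargs) -> "NetworkSpec":
        df = pd.read_csv(path)
        n = n_neurons or int(max(df["pre"].max(), df["post"].max())) + 1
        return cls(n_neurons=n, pre=df["pre"].to_numpy(), post=df["post"].to_numpy(),
                   weight=df["weight"].to_numpy(), delay=df["delay"].to_numpy(),
                   **kwargs)


@dataclass
class SpikeRecord:
    """Per-neuron ordered spike times (ms) over a simulation window."""

    times: np.ndarray        # spike times, ms
    neurons: np.ndarray      # emitting neuron per spike
    n_neurons: int
    duration: float

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.neurons = np.asarray(self.neurons, dtype=int)

    def spike_times(self, neuron: int) -> np.ndarray:
        return self.times[self.neurons == neuron]

    def counts(self, neurons=None, t_start: float = 0.0,
               t_stop: float | None = None) -> np.ndarray:
        """Spike counts per requested neuron within [t_start, t_stop)."""
        t_stop = self.duration if t_stop is None else t_stop
        neurons = np.arange(self.n_neurons) if neurons is None else np.asarray(neurons)
        mask = (self.times >= t_start) & (self.times < t_stop)
        binned = np.bincount(self.neurons[mask], minlength=self.n_neurons)
        return binned[neurons]

    def rates(self, neurons=None, t_start: float = 0.0,
              t_stop: float | None = None) -> np.ndarray:
        """Mean firing rates in Hz over the window."""
        t_stop = self.duration if t_stop is None else t_stop
        return self.counts(neurons, t_start, t_stop) * 1000.0 / (t_stop - t_start)
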
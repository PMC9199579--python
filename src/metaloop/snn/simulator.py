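"""Forward-Euler LIF integration with delta-current synapses and delay queues.

Two engines share the same neuron model:

* :func:`simulate_network` — reference single-network simulator supporting
  arbitrary integer synaptic delays (used for the small ant-brain network and
  for validating the integrator against the closed-form f-I curve).
* :class:`BatchedLIF` — vectorized engine integrating B same-topology
  networks side by side (unit delays), used by the testbeds where a whole
  population or episode batch is simulated per generation.

Membrane update per step: ``V += dt/tau * (-(V - V_rest) + R*I)`` plus the
summed synaptic jumps (``weight * weight_scale`` mV) arriving that step; a
neuron crossing threshold spikes, is reset and stays refractory for
``t_refractory``. Randomness enters only through Poisson background/input
spike trains, generated from the supplied generator.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

from ..errors import ContractError, MetaloopError
from .network import LIFParams, NetworkSpec, SpikeRecord

__all__ = ["simulate_network", "lif_rate", "dc_for_rate", "poisson_events",
           "BatchedLIF"]


def lif_rate(params: LIFParams, current: float) -> float:
    """Closed-form steady firing rate (Hz) of a LIF neuron under DC drive.

    ``rate = 1000 / (t_ref + tau * ln(RI / (RI - dV)))`` with
    ``dV = threshold - rest``; zero below rheobase.
    """
    RI = params.resistance * current
    dV = params.v_threshold - params.v_rest
    if RI <= dV:
        return 0.0
    isi = params.t_refractory + params.tau_m * np.log(RI / (RI - dV))
    return 1000.0 / isi


def dc_for_rate(params: LIFParams, rate_hz: float, dt: float = 0.1) -> float:
    """DC amplitude whose closed-form rate is ``rate_hz``.

    Rates at the refractory ceiling (``1000/t_ref``) would need unbounded
    current; the integration time is floored at half a step, which pins the
    discrete simulator to its maximum rate ``1000/(t_ref + dt)``.
    """
    dV = params.v_threshold - params.v_rest
    t_int = max(1000.0 / rate_hz - params.t_refractory, dt / 2.0)
    return dV / (1.0 - np.exp(-t_int / params.tau_m)) / params.resistance


def poisson_events(rate_hz, n_steps: int, dt: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Boolean (n_steps, ...) spike raster of independent Poisson trains."""
    p = np.asarray(rate_hz, dtype=float) * dt / 1000.0
    return rng.random(size=(n_steps,) + p.shape) < p


def simulate_network(
    net: NetworkSpec,
    input_currents,
    duration: float,
    dt: float = 0.1,
    rng: np.random.Generator | None = None,
    *,
    background_rate: float = 0.0,
    background_jump: float = 0.5,
    source_rates=None,
) -> SpikeRecord:
    """Integrate one network for ``duration`` ms; returns its spikes.

    ``input_currents`` is a per-neuron DC vector (length n), a
    ``(n_steps, n)`` array, or ``None``. Neurons listed in
    ``net.spike_sources`` do not integrate: they emit Poisson spikes at
    ``source_rates`` (Hz, aligned with ``net.spike_sources``). Background
    Poisson noise at ``background_rate`` Hz adds ``background_jump`` mV
    kicks to every non-source neuron.
    """
    p = net.params
    n = net.n_neurons
    n_steps = int(round(duration / dt))
    if abs(n_steps * dt - duration) > 1e-9:
        raise ContractError("dt must divide the simulation duration")
    rng = rng or np.random.default_rng(0)

    drive = np.zeros((1, n)) if input_currents is None else \
        np.atleast_2d(np.asarray(input_currents, dtype=float))
    if drive.shape[-1] != n:
        raise ContractError(f"input drive must cover all {n} neurons")

    source_mask = np.zeros(n, dtype=bool)
    src_rates = None
    if net.spike_sources is not None and len(net.spike_sources):
        source_mask[np.asarray(net.spike_sources, dtype=int)] = True
        if source_rates is not None:
            src_rates = np.asarray(source_rates, dtype=float)

    # synapses grouped by delay for the ring buffer
    delays = np.unique(net.delay) if net.n_synapses else np.array([1])
    max_delay = int(delays.max())
    by_delay = [(int(d), net.pre[net.delay == d], net.post[net.delay == d],
                 net.weight[net.delay == d] * net.weight_scale)
                for d in delays]

    V = np.full(n, p.v_rest)
    refrac = np.zeros(n, dtype=int)
    ref_steps = int(round(p.t_refractory / dt))
    buffer = np.zeros((max_delay + 1, n))
    spike_t, spike_n = [], []
    leak = dt / p.tau_m

    for t in range(n_steps):
        I_t = drive[t % drive.shape[0]]
        jumps = buffer[t % (max_delay + 1)]
        active = refrac == 0
        dv = leak * (-(V - p.v_rest) + p.resistance * I_t) + jumps
        V = np.where(active & ~source_mask, V + dv, V)
        if np.any(np.isnan(V)):
            bad = int(np.argmax(np.isnan(V)))
            raise MetaloopError(
                f"membrane potential of neuron {bad} became NaN at t={t * dt:.3f} ms")
        if background_rate > 0:
            kick = rng.random(n) < background_rate * dt / 1000.0
            V = np.where(active & ~source_mask & kick, V + background_jump, V)

        spiked = active & ~source_mask & (V >= p.v_threshold)
        if src_rates is not None:
            src_fire = rng.random(src_rates.size) < src_rates * dt / 1000.0
            fire_idx = np.asarray(net.spike_sources, dtype=int)[src_fire]
            spiked = spiked.copy()
            spiked[fire_idx] = True
        elif source_mask.any():
            pass  # silent sources

        idx = np.flatnonzero(spiked)
        if idx.size:
            spike_t.extend([(t + 1) * dt] * idx.size)
            spike_n.extend(idx.tolist())
            own = spiked & ~source_mask
            V[own] = p.v_reset
            refrac[own] = ref_steps + 1  # decremented below; t_ref full steps silent
            for d, pre, post, w in by_delay:
                sel = spiked[pre]
                if sel.any():
                    np.add.at(buffer[(t + d) % (max_delay + 1)], post[sel], w[sel])
        refrac = np.maximum(refrac - 1, 0)
        buffer[t % (max_delay + 1)] = 0.0

    return SpikeRecord(times=np.array(spike_t), neurons=np.array(spike_n),
                       n_neurons=n, duration=duration)


class BatchedLIF:
    """B same-topology LIF networks integrated in lockstep (unit delays).

    Synaptic input per step is assembled from up to two sources:

    * ``shared_jump`` — an (n, n) matrix of voltage jumps (already scaled to
      mV) common to all members, entry [i, j] = jump of neuron j when i fires;
    * ``member_jump`` — a (B, n, n) per-member jump tensor, or
      ``member_groups`` + ``member_weights`` for the sparse case where only a
      small readout edge set differs between members (groups map each target
      neuron to its source indices; weights are (B, n_edges) in jump units).

    Spike-source neurons (``source_mask``) never integrate; their spikes are
    passed into :meth:`step` each call.
    """

    def __init__(self, n_neurons: int, batch: int, params: LIFParams,
                 dt: float, *, shared_jump: np.ndarray | None = None,
                 member_jump: np.ndarray | None = None,
                 member_groups: list[tuple[int, np.ndarray]] | None = None,
                 member_weights: np.ndarray | None = None,
                 source_mask: np.ndarray | None = None):
        self.n = n_neurons
        self.B = batch
        self.p = params
        self.dt = dt
        self.leak = dt / params.tau_m
        self.ref_steps = int(round(params.t_refractory / dt))
        if shared_jump is not None and sparse.issparse(shared_jump):
            self._shared_T = sparse.csr_matrix(shared_jump.T)
            shared_jump = "sparse"
        else:
            self._shared_T = None
        self.shared_jump = shared_jump
        self.member_jump = member_jump
        self.member_groups = member_groups
        if member_groups is not None:
            offsets = np.cumsum([0] + [g[1].size for g in member_groups])
            self._group_slices = [slice(offsets[i], offsets[i + 1])
                                  for i in range(len(member_groups))]
            if member_weights is None or member_weights.shape != (batch, offsets[-1]):
                raise ContractError(
                    f"member_weights must be ({batch}, {offsets[-1]})")
        self.member_weights = member_weights
        self.source_mask = (np.zeros(n_neurons, dtype=bool)
                            if source_mask is None else source_mask)
        self.reset()

    def reset(self) -> None:
        self.V = np.full((self.B, self.n), self.p.v_rest)
        self.refrac = np.zeros((self.B, self.n), dtype=int)
        self.pending = np.zeros((self.B, self.n))   # jumps arriving next step

    def set_member_weights(self, weights: np.ndarray) -> None:
        self.member_weights = weights

    def step(self, ext_current=None, source_spikes=None,
             noise_jumps=None) -> np.ndarray:
        """Advance all members one step; returns the (B, n) spike mask.

        ``ext_current``: (n,) or (B, n) DC drive; ``source_spikes``: (B, n)
        boolean spikes of source neurons this step; ``noise_jumps``: (B, n)
        additive voltage kicks (background noise), applied to integrating
        neurons only.
        """
        has_sources = self.source_mask.any()
        integ = self.refrac == 0
        if has_sources:
            integ &= ~self.source_mask
        dv = self.pending
        dv -= self.leak * (self.V - self.p.v_rest)
        if ext_current is not None:
            dv += self.leak * self.p.resistance * np.asarray(ext_current, dtype=float)
        if noise_jumps is not None:
            dv += noise_jumps
        np.add(self.V, dv, out=self.V, where=integ)

        spiked = integ & (self.V >= self.p.v_threshold)
        own = spiked
        if source_spikes is not None:
            spiked = spiked | (source_spikes & self.source_mask[None, :])
        self.V[own] = self.p.v_reset
        self.refrac[own] = self.ref_steps + 1
        np.maximum(self.refrac - 1, 0, out=self.refrac)

        pending = np.zeros((self.B, self.n))
        if self.member_jump is not None:
            # spikes are sparse: scatter-add the firing neurons' weight rows
            bs, ns = np.nonzero(spiked)
            if bs.size:
                np.add.at(pending, bs, self.member_jump[bs, ns])
        if self._shared_T is not None or self.shared_jump is not None \
                or self.member_groups is not None:
            s = spiked.astype(float)
            if self._shared_T is not None:
                pending += (self._shared_T @ s.T).T
            elif self.shared_jump is not None:
                pending += s @ self.shared_jump
            if self.member_groups is not None:
                for (post, src), sl in zip(self.member_groups, self._group_slices):
                    pending[:, post] += (s[:, src] * self.member_weights[:, sl]).sum(axis=1)
        self.pending = pending
        return spiked
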
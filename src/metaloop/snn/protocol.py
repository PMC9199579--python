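"""Digit-presentation protocol for the spiking reservoir.

One trial is: a 100 ms warmup with background noise only (membranes settle),
then for each image a 500 ms presentation (input neurons emit Poisson spike
trains at the pixel-encoded rates) followed by a 200 ms cooling period with
no input. The per-image readout is the firing rate of each output cluster
during the presentation window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from ..errors import ContractError
from .encoding import encode_pixels_to_rates
from .network import NetworkSpec
from .simulator import BatchedLIF

__all__ = ["DigitProtocol", "run_digit_protocol", "run_digit_protocol_ensemble"]


@dataclass(frozen=True)
class DigitProtocol:
    warmup: float = 100.0          # ms, background only
    presentation: float = 500.0    # ms per image
    cooling: float = 200.0         # ms of silence between images
    background_rate: float = 5.0   # Hz Poisson noise on every neuron
    background_jump: float = 1.0   # mV kick per background event
    dt: float = 1.0                # ms integration step for this protocol

    def total_duration(self, n_images: int) -> float:
        return self.warmup + n_images * (self.presentation + self.cooling)


def _pixel_assignment(n_pixels: int, n_input: int) -> np.ndarray:
    """Evenly spaced pixel indices feeding the (possibly scaled) input layer."""
    if n_pixels < n_input:
        raise ContractError(
            f"images have {n_pixels} pixels but the network expects >= {n_input}")
    return np.linspace(0, n_pixels - 1, n_input).round().astype(int)


def run_digit_protocol_ensemble(
    net: NetworkSpec,
    readout_weights: np.ndarray,
    images: np.ndarray,
    protocol: DigitProtocol,
    rng: np.random.Generator,
) -> np.ndarray:
    """Run the protocol for a whole ensemble at once.

    ``readout_weights`` is (B, n_readout) in the builder's readout synapse
    order; every member simulates the same image batch with independent
    Poisson realizations. Returns per-member, per-image output-cluster rates
    of shape (B, n_images, 3).
    """
    readout_weights = np.atleast_2d(np.asarray(readout_weights, dtype=float))
    B = readout_weights.shape[0]
    images = np.atleast_2d(np.asarray(images, dtype=float))
    n_images = images.shape[0]
    dt = protocol.dt

    inp = net.population("input")
    clusters = [net.population(f"output_{c}") for c in range(3)]
    readout = net.synapse_groups["readout"]
    n_read = readout.stop - readout.start
    if readout_weights.shape[1] != n_read:
        raise ContractError(
            f"readout weight vectors must have {n_read} entries")

    # shared connectivity (everything except the readout block), in mV jumps
    shared_mask = np.ones(net.n_synapses, dtype=bool)
    shared_mask[readout] = False
    shared = sparse.csr_matrix(
        (net.weight[shared_mask] * net.weight_scale,
         (net.pre[shared_mask], net.post[shared_mask])),
        shape=(net.n_neurons, net.n_neurons))

    # readout block grouped per output neuron (contiguous by construction)
    groups = []
    r_pre = net.pre[readout]
    r_post = net.post[readout]
    k = 0
    while k < n_read:
        post = int(r_post[k])
        j = k
        while j < n_read and r_post[j] == post:
            j += 1
        groups.append((post, r_pre[k:j]))
        k = j

    source_mask = np.zeros(net.n_neurons, dtype=bool)
    source_mask[inp] = True
    engine = BatchedLIF(
        net.n_neurons, B, net.params, dt, shared_jump=shared,
        member_groups=groups,
        member_weights=readout_weights * net.weight_scale,
        source_mask=source_mask)

    noise_p = protocol.background_rate * dt / 1000.0
    integ = ~source_mask

    def run_window(n_steps: int, input_rates: np.ndarray | None,
                   count_clusters: bool):
        counts = np.zeros((B, 3)) if count_clusters else None
        src_p = None if input_rates is None else input_rates * dt / 1000.0
        for _ in range(n_steps):
            noise = (rng.random((B, net.n_neurons)) < noise_p) \
                .astype(float) * protocol.background_jump
            noise[:, ~integ] = 0.0
            src = None
            if src_p is not None:
                src = np.zeros((B, net.n_neurons), dtype=bool)
                src[:, inp] = rng.random((B, inp.size)) < src_p[None, :]
            spiked = engine.step(noise_jumps=noise, source_spikes=src)
            if count_clusters:
                for c, cl in enumerate(clusters):
                    counts[:, c] += spiked[:, cl].sum(axis=1)
        return counts

    run_window(int(round(protocol.warmup / dt)), None, False)
    assign = _pixel_assignment(images.shape[1], inp.size)
    rates = np.empty((B, n_images, 3))
    pres_steps = int(round(protocol.presentation / dt))
    cool_steps = int(round(protocol.cooling / dt))
    for i, image in enumerate(images):
        input_rates = encode_pixels_to_rates(image[assign])
        counts = run_window(pres_steps, input_rates, True)
        rates[:, i, :] = counts * 1000.0 / protocol.presentation
        run_window(cool_steps, None, False)
    return rates


def run_digit_protocol(net: NetworkSpec, images: np.ndarray,
                       protocol: DigitProtocol | None = None,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Single-network protocol run; returns (n_images, 3) cluster rates."""
    protocol = protocol or DigitProtocol()
    rng = rng or np.random.default_rng(0)
    readout = net.synapse_groups["readout"]
    weights = net.weight[readout][None, :]
    return run_digit_protocol_ensemble(net, weights, images, protocol, rng)[0]
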
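"""Deterministic builders for the three task networks.

Each builder emits a :class:`NetworkSpec` whose synapse table has a fixed,
documented block order (see ``synapse_groups``), so the flat weight vectors
the optimizers move always land on the same synapses.
"""

from __future__ import annotations

import numpy as np

from ..errors import ConfigurationError, ContractError
from .network import LIFParams, NetworkSpec

__all__ = ["build_reservoir", "build_ant_brain", "build_mc_policy"]


def _scaled(count: int, scale: float, minimum: int = 0) -> int:
    return max(minimum, int(round(count * scale)))


def build_reservoir(scale: float = 1.0, rng: np.random.Generator | None = None,
                    *, weight_scale: float = 0.05) -> NetworkSpec:
    """Liquid-state-machine reservoir for 3-class digit classification.

    At scale 1: 768 input neurons (one per pixel, spike sources), a reservoir
    of 1600 excitatory + 400 inhibitory neurons with maximal outdegrees of 6%
    (excitatory) and 8% (inhibitory) of the reservoir, and 3 output clusters
    of 12 neurons (10 excitatory, 2 inhibitory) that are recurrently
    connected within but never across clusters. Every output neuron draws
    exactly ``round(800 * scale)`` reservoir sources — the readout synapses
    the ensemble optimizer trains; at scale 1 that is 800 x 12 x 3 = 28 800.
    ``scale`` shrinks every population proportionally (ratios preserved).

    Weights are sampled from the stated normals (mu 70, sigma 50 for
    excitatory sources; mu -90, sigma 50 for inhibitory), then sign-clamped
    to their population type. Synapse block order: ``input_to_reservoir``,
    ``reservoir_recurrent``, ``output_recurrent``, ``readout`` (readout
    ordered cluster-major, then neuron, then source draw order).
    """
    rng = rng or np.random.default_rng(0)
    if not 0 < scale <= 1:
        raise ConfigurationError("scale must lie in (0, 1]")

    n_input = _scaled(768, scale, minimum=1)
    n_exc = _scaled(1600, scale, minimum=1)
    n_inh = _scaled(400, scale, minimum=1)
    n_res = n_exc + n_inh
    cluster_exc = _scaled(10, scale)
    cluster_inh = _scaled(2, scale)
    if cluster_exc + cluster_inh < 1:
        raise ConfigurationError(
            f"scale {scale} produces an empty output cluster")
    n_cluster = cluster_exc + cluster_inh
    k_read = _scaled(800, scale, minimum=1)

    inp = np.arange(n_input)
    res = n_input + np.arange(n_res)
    res_exc, res_inh = res[:n_exc], res[n_exc:]
    clusters = [n_input + n_res + c * n_cluster + np.arange(n_cluster)
                for c in range(3)]
    n_neurons = n_input + n_res + 3 * n_cluster

    excitatory = np.ones(n_neurons, dtype=bool)
    excitatory[res_inh] = False
    for c in clusters:
        excitatory[c[cluster_exc:]] = False

    def draw_weights(pre_ids, size):
        exc = excitatory[pre_ids]
        w = np.where(exc, rng.normal(70.0, 50.0, size), rng.normal(-90.0, 50.0, size))
        return np.where(exc, np.abs(w), -np.abs(w))  # sign fixed by neuron type

    pre_l, post_l, w_l = [], [], []

    def connect_out(pre_ids, targets, outdegree):
        """Each pre neuron projects to ``outdegree`` distinct targets."""
        for pre in pre_ids:
            choice = rng.choice(targets, size=outdegree, replace=False)
            pre_l.append(np.full(outdegree, pre))
            post_l.append(choice)
        w = draw_weights(np.repeat(pre_ids, outdegree), len(pre_ids) * outdegree)
        w_l.append(w)

    groups: dict[str, slice] = {}

    def mark(name, start):
        end = sum(a.size for a in pre_l)
        groups[name] = slice(start, end)
        return end

    # input -> reservoir: every pixel neuron projects like an excitatory cell
    k_in = max(1, int(np.floor(0.06 * n_res)))
    connect_out(inp, res, k_in)
    end = mark("input_to_reservoir", 0)

    # reservoir recurrent with the 6% / 8% outdegree caps
    k_exc = max(1, int(np.floor(0.06 * n_res)))
    k_inh = max(1, int(np.floor(0.08 * n_res)))
    connect_out(res_exc, res, k_exc)
    connect_out(res_inh, res, k_inh)
    end = mark("reservoir_recurrent", end)

    # output clusters: all-to-all within, none across
    for c in clusters:
        for i in c:
            others = c[c != i]
            if others.size:
                pre_l.append(np.full(others.size, i))
                post_l.append(others)
                w_l.append(draw_weights(np.full(others.size, i), others.size))
    end = mark("output_recurrent", end)

    # readout: each output neuron draws exactly k_read reservoir sources
    for c in clusters:
        for neuron in c:
            src = rng.choice(res, size=k_read, replace=False)
            pre_l.append(src)
            post_l.append(np.full(k_read, neuron))
            w_l.append(draw_weights(src, k_read))
    end = mark("readout", end)

    pre = np.concatenate(pre_l)
    post = np.concatenate(post_l)
    weight = np.concatenate(w_l)
    populations = {"input": inp, "reservoir": res, "reservoir_exc": res_exc,
                   "reservoir_inh": res_inh,
                   **{f"output_{c}": cl for c, cl in enumerate(clusters)},
                   "output": np.concatenate(clusters)}
    return NetworkSpec(
        n_neurons=n_neurons, pre=pre, post=post, weight=weight,
        delay=np.ones(pre.size, dtype=int), excitatory=excitatory,
        populations=populations, spike_sources=inp,
        weight_scale=weight_scale, params=LIFParams(),
        synapse_groups=groups)


def build_ant_brain(weights, delays, *, weight_scale: float = 0.25) -> NetworkSpec:
    """Three-layer ant controller: 12 inputs, 10 hidden, 4 outputs.

    The 250 synapses are, in fixed order: 11 sensory inputs x 10 hidden
    (110, pre-major), heartbeat -> hidden (10), hidden recurrent all-to-all
    without self-loops (90, pre-major), hidden x 4 outputs (40, pre-major).
    ``weights`` and ``delays`` are length-250 vectors in exactly that order;
    delays are integer simulation steps.
    """
    weights = np.asarray(weights, dtype=float)
    delays = np.asarray(delays)
    if weights.size != 250 or delays.size != 250:
        raise ContractError(
            f"expected 250 weights and 250 delays, got {weights.size} and {delays.size}")

    sensory = np.arange(11)
    heartbeat = 11
    hidden = 12 + np.arange(10)
    output = 22 + np.arange(4)

    pre, post = [], []
    for s in sensory:                      # 110
        for h in hidden:
            pre.append(s); post.append(h)
    for h in hidden:                       # 10
        pre.append(heartbeat); post.append(h)
    for h1 in hidden:                      # 90
        for h2 in hidden:
            if h1 != h2:
                pre.append(h1); post.append(h2)
    for h in hidden:                       # 40
        for o in output:
            pre.append(h); post.append(o)

    groups = {"input_to_hidden": slice(0, 110),
              "heartbeat_to_hidden": slice(110, 120),
              "hidden_recurrent": slice(120, 210),
              "hidden_to_output": slice(210, 250)}
    populations = {"sensory": sensory, "heartbeat": np.array([heartbeat]),
                   "hidden": hidden, "output": output}
    return NetworkSpec(
        n_neurons=26, pre=np.array(pre), post=np.array(post),
        weight=weights, delay=delays.astype(int),
        populations=populations, weight_scale=weight_scale,
        params=LIFParams(), synapse_groups=groups)


def build_mc_policy(weights, *, weight_scale: float = 0.5) -> NetworkSpec:
    """Feed-forward mountain-car policy: 60 inputs -> 5 hidden -> 3 outputs.

    Inputs 0..29 are the position bins, 30..59 the velocity bins; the active
    bin neuron is driven by a DC current calibrated (via the closed-form f-I
    curve) toward a 500 Hz firing rate. The 315 weights are input x hidden
    (300, pre-major) followed by hidden x output (15, pre-major). All
    synapses have unit delay.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.size != 315:
        raise ContractError(f"expected 315 weights, got {weights.size}")

    inputs = np.arange(60)
    hidden = 60 + np.arange(5)
    output = 65 + np.arange(3)
    pre, post = [], []
    for i in inputs:
        for h in hidden:
            pre.append(i); post.append(h)
    for h in hidden:
        for o in output:
            pre.append(h); post.append(o)

    groups = {"input_to_hidden": slice(0, 300), "hidden_to_output": slice(300, 315)}
    populations = {"input": inputs, "position_bins": inputs[:30],
                   "velocity_bins": inputs[30:], "hidden": hidden,
                   "output": output}
    return NetworkSpec(
        n_neurons=68, pre=np.array(pre), post=np.array(post),
        weight=weights, delay=np.ones(315, dtype=int),
        populations=populations, weight_scale=weight_scale,
        params=LIFParams(), synapse_groups=groups)
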
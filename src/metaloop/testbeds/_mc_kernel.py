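"""Compiled mountain-car rollout: environment + LIF policy fused per batch.

Mirrors the vectorized engine's update order (leak + external drive +
pending synaptic jumps, threshold, reset, refractory countdown, unit-delay
propagation) in one JIT-compiled loop so whole populations of episodes run
in milliseconds. The numpy engine remains the reference implementation; a
test asserts the two paths produce identical episodes.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def mc_rollout_kernel(J, pos0, vel0, max_steps, interval_steps,
                      dc_drive, leak, v_rest, v_thr, v_reset, ref_steps,
                      pos_lo, pos_hi, vel_lo, vel_hi, goal,
                      n_bins, enc_vlo, enc_vhi, default_action):
    """Roll out B policies/episodes; returns (traces, steps_to_goal).

    ``J`` is (B, n, n) voltage jumps (pre, post); inputs are neurons
    [0, 2*n_bins), hidden the next 5, outputs the last 3. ``dc_drive`` is
    the per-step voltage contribution of the DC generator on the active
    bin neurons (leak * R * I_dc).
    """
    B, n, _ = J.shape
    n_out = 3
    out0 = n - n_out
    V = np.full((B, n), v_rest)
    refrac = np.zeros((B, n), dtype=np.int64)
    pending = np.zeros((B, n))
    pos = pos0.copy()
    vel = vel0.copy()
    done = np.zeros(B, dtype=np.bool_)
    traces = np.empty((B, max_steps))
    steps_to_goal = np.full(B, max_steps, dtype=np.int64)
    pw = (pos_hi - pos_lo) / n_bins
    vw = (enc_vhi - enc_vlo) / n_bins

    for t in range(max_steps):
        # active encoding neurons per batch entry
        counts = np.zeros((B, n_out), dtype=np.int64)
        pbin = np.empty(B, dtype=np.int64)
        vbin = np.empty(B, dtype=np.int64)
        for b in range(B):
            pb = int(np.floor((pos[b] - pos_lo) / pw))
            pbin[b] = min(max(pb, 0), n_bins - 1)
            vb = int(np.floor((vel[b] - enc_vlo) / vw))
            vbin[b] = n_bins + min(max(vb, 0), n_bins - 1)

        for _ in range(interval_steps):
            for b in range(B):
                # integrate + detect spikes
                for i in range(n):
                    if refrac[b, i] == 0:
                        dv = pending[b, i] - leak * (V[b, i] - v_rest)
                        if i == pbin[b] or i == vbin[b]:
                            dv += dc_drive
                        V[b, i] += dv
                    pending[b, i] = 0.0
                for i in range(n):
                    if refrac[b, i] == 0 and V[b, i] >= v_thr:
                        V[b, i] = v_reset
                        refrac[b, i] = ref_steps + 1
                        for j in range(n):
                            pending[b, j] += J[b, i, j]
                        if i >= out0:
                            counts[b, i - out0] += 1
                    if refrac[b, i] > 0:
                        refrac[b, i] -= 1

        all_done = True
        for b in range(B):
            # winner-take-all action, then one environment step
            best, best_c = default_action, 0
            for a in range(n_out):
                if counts[b, a] > best_c:
                    best, best_c = a, counts[b, a]
            if not done[b]:
                v = vel[b] + 0.001 * (best - 1) - 0.0025 * np.cos(3.0 * pos[b])
                v = min(max(v, vel_lo), vel_hi)
                p = min(max(pos[b] + v, pos_lo), pos_hi)
                vel[b] = v
                pos[b] = p
                if p >= goal:
                    steps_to_goal[b] = t + 1
                    done[b] = True
            traces[b, t] = pos[b]
            if not done[b]:
                all_done = False
        if all_done:
            for b in range(B):
                for tt in range(t + 1, max_steps):
                    traces[b, tt] = pos[b]
            break

    return traces, steps_to_goal
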
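"""Encoders and decoders between task variables and spiking activity."""

from __future__ import annotations

import numpy as np

from ..errors import ContractError

__all__ = ["encode_pixels_to_rates", "bin_index", "winner_take_all"]


def encode_pixels_to_rates(pixels) -> np.ndarray:
    """Affine rate code: pixel intensity 0..255 mapped to 1..100 Hz."""
    p = np.asarray(pixels, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 255):
        raise ContractError("pixel values must lie in [0, 255]")
    return 1.0 + 99.0 * p / 255.0


def bin_index(value: float, low: float, high: float, n: int) -> int:
    """Discretize a continuous value into one of ``n`` equal-width bins.

    Bin width is ``(high - low) / n``; the index is floored and clamped to
    ``[0, n-1]`` so ``value == high`` lands in the last bin.
    """
    if not low < high:
        raise ContractError("bin range needs low < high")
    if n < 1:
        raise ContractError("need at least one bin")
    w = (high - low) / n
    return int(np.clip(np.floor((value - low) / w), 0, n - 1))


def winner_take_all(spike_counts, default: int = 0) -> int:
    """Index of the most active output unit.

    Ties break toward the lowest index; an all-zero count vector returns the
    configured ``default`` action index.
    """
    counts = np.asarray(spike_counts)
    if counts.size == 0:
        raise ContractError("empty spike count vector")
    if not counts.any():
        return default
    return int(np.argmax(counts))
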
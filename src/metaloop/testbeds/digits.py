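"""Synthetic digit classification with an ensemble-Kalman-trained reservoir.

The digit stand-in renders three distinct high-contrast stripe glyphs on a
768-pixel canvas with salt noise, guaranteeing linear separability at the
default noise level. Training optimizes only the reservoir-to-output
readout weights: every ensemble member runs the full presentation protocol
on the same image batch, its per-image softmax outputs are assimilated
toward the one-hot labels by the regularized ensemble Kalman update, and the
worst members are replaced by perturbed copies of the best.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import ConfigurationError
from ..fitness import mse_fitness, softmax
from ..optimizers.enkf import (EnKFConfig, denormalize_from_unit, enkf_update,
                               normalize_to_unit, rank_replace_perturb)
from ..snn.builders import build_reservoir
from ..snn.network import NetworkSpec
from ..snn.protocol import DigitProtocol, run_digit_protocol_ensemble

__all__ = ["synthetic_digits", "nearest_centroid_accuracy",
           "ReservoirTrainingResult", "train_reservoir", "READOUT_BOUNDS"]

READOUT_BOUNDS = (-150.0, 150.0)


def synthetic_digits(n_per_class: int, n_classes: int = 3, n_pixels: int = 768,
                     noise: float = 0.1, rng: np.random.Generator | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Balanced synthetic glyph dataset; pixel values in [0, 255].

    Class ``k`` lights stripes ``k`` and ``k + n_classes`` of ``2 *
    n_classes`` equal canvas stripes at full intensity (scaled by a random
    per-image contrast in [0.75, 1]); ``noise`` is the per-pixel probability
    of replacement with a uniform random intensity (salt noise). Returns
    ``(images (N, n_pixels), labels (N,))`` with exactly ``n_per_class``
    images per class, deterministically from ``rng``.
    """
    if n_classes < 2:
        raise ConfigurationError("need at least 2 classes")
    rng = rng or np.random.default_rng(0)
    stripe = (np.arange(n_pixels) * (2 * n_classes)) // n_pixels
    templates = np.stack([
        np.where((stripe == k) | (stripe == k + n_classes), 255.0, 0.0)
        for k in range(n_classes)])
    images, labels = [], []
    for k in range(n_classes):
        for _ in range(n_per_class):
            img = templates[k] * rng.uniform(0.75, 1.0)
            salt = rng.random(n_pixels) < noise
            img = np.where(salt, rng.uniform(0, 255, n_pixels), img)
            images.append(img)
            labels.append(k)
    return np.array(images), np.array(labels)


def nearest_centroid_accuracy(images: np.ndarray, labels: np.ndarray) -> float:
    """Leave-nothing-out nearest-centroid accuracy (separability check)."""
    classes = np.unique(labels)
    centroids = np.stack([images[labels == c].mean(axis=0) for c in classes])
    d = ((images[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return float((classes[np.argmin(d, axis=1)] == labels).mean())


@dataclass
class ReservoirTrainingResult:
    best_fitness: np.ndarray           # per generation, over the ensemble
    mean_fitness: np.ndarray
    test_fitness: dict[int, float] = field(default_factory=dict)
    weights: np.ndarray | None = None  # final ensemble (n_ens, n_readout)
    net: NetworkSpec | None = None


def _batch_fitness(rates: np.ndarray, labels: np.ndarray, n_classes: int,
                   temperature: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-member mean fitness and concatenated softmax predictions.

    ``rates`` is (B, n_images, n_classes) output-cluster rates; the softmax
    over (temperature-scaled) rates is the per-image prediction.
    """
    B, n_images, _ = rates.shape
    onehot = np.eye(n_classes)[labels]
    fitness = np.empty(B)
    preds = np.empty((B, n_images * n_classes))
    for b in range(B):
        p = np.stack([softmax(rates[b, i] / temperature) for i in range(n_images)])
        preds[b] = p.ravel()
        fitness[b] = np.mean([mse_fitness(onehot[i], p[i]) for i in range(n_images)])
    return fitness, preds


def train_reservoir(
    scale: float = 0.1,
    *,
    seed: int = 0,
    n_ensemble: int = 20,
    generations: int = 30,
    batch_size: int = 10,
    n_classes: int = 3,
    n_pixels: int = 768,
    noise: float = 0.1,
    enkf_config: EnKFConfig | None = None,
    protocol: DigitProtocol | None = None,
    softmax_temperature: float = 5.0,
    init_sigma: float = 50.0,
    test_every: int = 10,
    stop_at_fitness: float | None = None,
) -> ReservoirTrainingResult:
    """Train readout weights of a scaled reservoir on synthetic digits.

    Per generation: a balanced batch of ``batch_size`` images is drawn, every
    ensemble member simulates the full presentation protocol, softmax
    predictions and ``1 - MSE`` fitnesses are computed, the ensemble is
    moved by the regularized Kalman update toward the one-hot targets
    (parameters normalized to [0, 1] over the fixed readout bounds), and the
    worst 10% of members are replaced by noisy copies of the best 10%.
    Every ``test_every``-th generation the best member is scored on a
    held-out batch.
    """
    rng = np.random.default_rng(seed)
    config = enkf_config or EnKFConfig(gamma=0.5, replace_fraction=0.1,
                                       perturb_scale=0.02,
                                       normalize_bounds=READOUT_BOUNDS)
    net = build_reservoir(scale, rng)
    readout = net.synapse_groups["readout"]
    n_read = readout.stop - readout.start
    proto = protocol or DigitProtocol()

    # training/held-out pools
    train_x, train_y = synthetic_digits(20, n_classes, n_pixels, noise, rng)
    test_x, test_y = synthetic_digits(4, n_classes, n_pixels, noise, rng)

    # zero-mean readout init with enough spread that member predictions differ
    # (the ensemble update is driven entirely by prediction covariance)
    weights = np.clip(rng.normal(0.0, init_sigma, size=(n_ensemble, n_read)),
                      *READOUT_BOUNDS)

    best_hist, mean_hist, test_hist = [], [], {}
    for gen in range(generations):
        order = rng.permutation(train_x.shape[0])[:batch_size]
        images, labels = train_x[order], train_y[order]
        rates = run_digit_protocol_ensemble(net, weights, images, proto, rng)
        fitness, preds = _batch_fitness(rates, labels, n_classes,
                                        softmax_temperature)
        best_hist.append(float(fitness.max()))
        mean_hist.append(float(fitness.mean()))
        if stop_at_fitness is not None and fitness.max() > stop_at_fitness:
            break

        if test_every and (gen + 1) % test_every == 0:
            best = weights[np.argmax(fitness)][None, :]
            t_rates = run_digit_protocol_ensemble(net, best, test_x, proto, rng)
            t_fit, _ = _batch_fitness(t_rates, test_y, n_classes,
                                      softmax_temperature)
            test_hist[gen + 1] = float(t_fit[0])

        target = np.eye(n_classes)[labels].ravel()
        u = normalize_to_unit(weights, READOUT_BOUNDS)
        u = enkf_update(u, preds, target, config.gamma)
        u = rank_replace_perturb(u, fitness, config.replace_fraction,
                                 config.perturb_scale, rng)
        weights = np.clip(denormalize_from_unit(u, READOUT_BOUNDS),
                          *READOUT_BOUNDS)

    return ReservoirTrainingResult(
        best_fitness=np.array(best_hist), mean_fitness=np.array(mean_hist),
        test_fitness=test_hist, weights=weights, net=net)
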
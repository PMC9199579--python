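"""Outer-loop optimizers, each registered by name for the run configuration.

``natural-evolution-strategies`` and ``parallel-tempering`` are declared but
unimplemented: requesting them raises with a pointer to the implemented set.
"""

from __future__ import annotations

from ..errors import ConfigurationError
from .base import Optimizer
from .enkf import (EnKFConfig, EnKFOptimizer, denormalize_from_unit, enkf_update,
                   normalize_to_unit, rank_replace_perturb)
from .ga import GAConfig, GAOptimizer, HallOfFame, ga_step
from .es import ESConfig, ESOptimizer, es_step, rank_standardize
from .gradient import (GDConfig, GradientOptimizer, MultiGradientOptimizer,
                       estimate_gradient, gradient_step, multi_gradient_step)
from .annealing import SAConfig, SAOptimizer, cooling, sa_accept, sa_step
from .crossentropy import CEConfig, CEOptimizer, ce_step
from .gridsearch import GridConfig, GridOptimizer, grid_generate

__all__ = [
    "Optimizer", "OPTIMIZERS", "make_optimizer", "registered_optimizers",
    "EnKFConfig", "EnKFOptimizer", "enkf_update", "rank_replace_perturb",
    "normalize_to_unit", "denormalize_from_unit",
    "GAConfig", "GAOptimizer", "HallOfFame", "ga_step",
    "ESConfig", "ESOptimizer", "es_step", "rank_standardize",
    "GDConfig", "GradientOptimizer", "MultiGradientOptimizer",
    "gradient_step", "multi_gradient_step", "estimate_gradient",
    "SAConfig", "SAOptimizer", "sa_step", "sa_accept", "cooling",
    "CEConfig", "CEOptimizer", "ce_step",
    "GridConfig", "GridOptimizer", "grid_generate",
]

_CONFIG_CLASSES = {
    "enkf": EnKFConfig,
    "genetic-algorithm": GAConfig,
    "evolution-strategies": ESConfig,
    "gradient-ascent": GDConfig,
    "multi-gradient-ascent": GDConfig,
    "simulated-annealing": SAConfig,
    "cross-entropy": CEConfig,
    "grid-search": GridConfig,
}

OPTIMIZERS = {
    "enkf": EnKFOptimizer,
    "genetic-algorithm": GAOptimizer,
    "evolution-strategies": ESOptimizer,
    "gradient-ascent": GradientOptimizer,
    "multi-gradient-ascent": MultiGradientOptimizer,
    "simulated-annealing": SAOptimizer,
    "cross-entropy": CEOptimizer,
    "grid-search": GridOptimizer,
}

_UNIMPLEMENTED = ("natural-evolution-strategies", "parallel-tempering")


def registered_optimizers() -> list[str]:
    return sorted(OPTIMIZERS)


def make_optimizer(name: str, params: dict | None = None) -> Optimizer:
    """Instantiate a registered optimizer from config-file parameters."""
    params = dict(params or {})
    if name in _UNIMPLEMENTED:
        raise ConfigurationError(
            f"optimizer {name!r} is declared but not implemented; "
            f"registered optimizers: {registered_optimizers()}")
    if name not in OPTIMIZERS:
        raise ConfigurationError(
            f"unknown optimizer {name!r}; registered optimizers: "
            f"{registered_optimizers()}")
    cls = OPTIMIZERS[name]
    if name == "enkf":
        target = params.pop("target", None)
        if target is None:
            raise ConfigurationError("the enkf optimizer requires a 'target' vector")
        if "normalize_bounds" in params and params["normalize_bounds"] is not None:
            params["normalize_bounds"] = tuple(params["normalize_bounds"])
        return cls(EnKFConfig(**params), target=target)
    if name == "multi-gradient-ascent":
        n_individuals = params.pop("n_individuals", 4)
        n_cloud = params.pop("n_cloud", 64)
        params.setdefault("mode", "multi")
        return cls(GDConfig(**params), n_individuals=n_individuals, n_cloud=n_cloud)
    config_cls = _CONFIG_CLASSES[name]
    if "resolution" in params and isinstance(params["resolution"], list):
        params["resolution"] = tuple(params["resolution"])
    return cls(config_cls(**params))
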
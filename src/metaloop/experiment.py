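"""Two-loop experiment orchestration.

``run_experiment`` wires a registered optimizee (inner loop) to a registered
optimizer (outer loop): every generation is evaluated in an embarrassingly
parallel fashion, scalarized with the configured fitness weights, appended
to the trajectory, and handed to the optimizer for the next population;
bounds are re-applied after every optimizer step. The finished trajectory
is persisted to the results path (self-describing store + CSV export).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError
from .evaluation import Optimizee, evaluate_generation
from .external import ExternalOptimizee
from .optimizers import make_optimizer
from .parameters import Individual, ParameterEntry, ParameterSpec
from .trajectory import Trajectory, persist_trajectory

__all__ = ["ExperimentConfig", "run_experiment", "make_optimizee",
           "registered_optimizees", "OPTIMIZEES"]


# ---------------------------------------------------------------------------
# optimizee registry


def _make_benchmark(params: dict) -> Optimizee:
    from .testbeds.benchmarks import BenchmarkOptimizee
    return BenchmarkOptimizee(**params)


def _make_sphere(params: dict) -> Optimizee:
    return _make_benchmark({"name": "sphere", **params})


def _make_rastrigin(params: dict) -> Optimizee:
    return _make_benchmark({"name": "rastrigin", **params})


def _make_external(params: dict) -> Optimizee:
    spec = ParameterSpec.from_dict(params["parameters"])
    return ExternalOptimizee(command=params["command"], spec=spec,
                             workdir=params.get("workdir", "external-exchange"))


class MCPolicyOptimizee(Optimizee):
    """One mountain-car training episode per evaluation (serial framework
    path; the vectorized evolution lives in ``testbeds.mountain_car``)."""

    def __init__(self, train_steps: int = 110, dt: float = 0.1):
        self.train_steps = train_steps
        self.dt = dt

    def parameter_spec(self) -> ParameterSpec:
        from .testbeds.mountain_car import mc_parameter_spec
        return mc_parameter_spec()

    def simulate(self, individual: Individual, rng) -> np.ndarray:
        from .testbeds.mountain_car import run_mc_episode
        trace, _ = run_mc_episode(individual.values["weights"],
                                  max_steps=self.train_steps, rng=rng, dt=self.dt)
        return np.array([trace.max()])


class ToyCellOptimizee(Optimizee):
    """Trace-fitting against internally generated reference recordings."""

    def __init__(self, fitness: str = "square"):
        from .testbeds.toy_cell import DEFAULT_CLAMPS, ToyCellParams, toy_cell_trace
        self.mode = fitness
        self.truth = ToyCellParams()
        self.clamps = DEFAULT_CLAMPS
        self.reference = [toy_cell_trace(self.truth, c) for c in self.clamps]

    def parameter_spec(self) -> ParameterSpec:
        from .testbeds.toy_cell import FREE_BOUNDS
        return ParameterSpec(tuple(
            ParameterEntry(name, 1, lo, hi)
            for name, (lo, hi) in FREE_BOUNDS.items()))

    def simulate(self, individual: Individual, rng) -> np.ndarray:
        from .fitness import (VoltageTrace, spike_feature_fitness,
                              trace_square_loss)
        from .testbeds.toy_cell import toy_cell_traces_batch
        g = individual.values["g_leak"]
        E = individual.values["e_leak"]
        out = []
        for clamp, ref in zip(self.clamps, self.reference):
            trace = VoltageTrace(
                toy_cell_traces_batch(g, E, self.truth, clamp, 400.0, 0.1)[0], 0.1)
            if self.mode == "square":
                out.append(trace_square_loss(ref, trace))
            else:
                L, S = spike_feature_fitness(ref, trace, -20.0)
                out.extend([-L, -abs(S)])
        return np.array(out)


OPTIMIZEES = {
    "sphere": _make_sphere,
    "rastrigin": _make_rastrigin,
    "external": _make_external,
    "mc-policy": lambda params: MCPolicyOptimizee(**params),
    "toy-cell": lambda params: ToyCellOptimizee(**params),
}


def registered_optimizees() -> list[str]:
    return sorted(OPTIMIZEES)


def make_optimizee(name: str, params: dict | None = None) -> Optimizee:
    if name not in OPTIMIZEES:
        raise ConfigurationError(
            f"unknown optimizee {name!r}; registered optimizees: "
            f"{registered_optimizees()}")
    return OPTIMIZEES[name](dict(params or {}))


# ---------------------------------------------------------------------------
# configuration


@dataclass
class ExperimentConfig:
    optimizee_name: str
    optimizer_name: str
    optimizee_params: dict = field(default_factory=dict)
    optimizer_params: dict = field(default_factory=dict)
    name: str = "experiment"
    n_pop: int = 16
    n_generations: int = 10
    weights: tuple[float, ...] = (1.0,)
    n_workers: int = 1
    seed: int = 0
    results_path: str | None = None

    def __post_init__(self):
        if self.n_pop < 1:
            raise ConfigurationError("population size must be >= 1")
        if self.n_generations < 1:
            raise ConfigurationError("n_generations must be >= 1")
        self.weights = tuple(float(w) for w in self.weights)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        exp = raw.get("experiment", {})
        oe = raw.get("optimizee", {})
        oz = raw.get("optimizer", {})
        if "name" not in oe or "name" not in oz:
            raise ConfigurationError(
                "config must name both an optimizee and an optimizer")
        return cls(
            optimizee_name=oe["name"], optimizer_name=oz["name"],
            optimizee_params=oe.get("params", {}) or {},
            optimizer_params=oz.get("params", {}) or {},
            name=exp.get("name", "experiment"),
            n_pop=int(exp.get("population", 16)),
            n_generations=int(exp.get("n_generations", 10)),
            weights=tuple(exp.get("weights", [1.0])),
            n_workers=int(exp.get("workers", 1)),
            seed=int(exp.get("seed", 0)),
            results_path=exp.get("results"))

    def snapshot(self) -> dict:
        return {
            "name": self.name, "optimizee": self.optimizee_name,
            "optimizee_params": self.optimizee_params,
            "optimizer": self.optimizer_name,
            "optimizer_params": self.optimizer_params,
            "n_pop": self.n_pop, "n_generations": self.n_generations,
            "weights": list(self.weights), "n_workers": self.n_workers,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# the run loop


def run_experiment(config: ExperimentConfig) -> Trajectory:
    """Run the two-loop optimization described by ``config``.

    Generations proceed evaluate -> optimizer step -> bounds until
    ``n_generations`` is reached (or a one-shot optimizer such as grid
    search declares itself finished). The trajectory is persisted to the
    results path when one is configured.
    """
    optimizee = make_optimizee(config.optimizee_name, config.optimizee_params)
    optimizer = make_optimizer(config.optimizer_name, config.optimizer_params)
    rng = np.random.default_rng(config.seed)
    spec = optimizee.parameter_spec()

    population = optimizer.initialize(optimizee, config.n_pop, rng)
    population = [optimizee.bounding_func(ind) for ind in population]
    snapshot = config.snapshot()
    snapshot["n_pop"] = len(population)  # grid search sets its own size
    traj = Trajectory(config=snapshot, seed=config.seed)

    for gen in range(config.n_generations):
        records = evaluate_generation(
            population, optimizee, weights=config.weights,
            experiment_seed=config.seed, generation=gen,
            n_workers=config.n_workers)
        traj.append(population, records)
        if gen == config.n_generations - 1 or optimizer.finished:
            break
        population = optimizer.step(spec, population, records, rng)
        population = [optimizee.bounding_func(ind) for ind in population]
        if optimizer.finished:
            break

    if config.results_path:
        outdir = Path(config.results_path)
        outdir.mkdir(parents=True, exist_ok=True)
        persist_trajectory(traj, outdir / f"{config.name}.h5")
        traj.export_csv(outdir / f"{config.name}.csv")
    return traj
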
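"""Generation-indexed history of a two-loop run, with HDF5 persistence.

The trajectory is the append-only record the framework keeps of every
generation: the individuals that were evaluated, their fitness vectors, the
scalarized fitness, and the per-evaluation seeds. It is self-describing on
disk (config snapshot + per-generation tables) and round-trips exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .errors import ContractError, TrajectoryLoadError
from .parameters import Individual

__all__ = ["FitnessRecord", "GenerationRecord", "Trajectory",
           "persist_trajectory", "load_trajectory"]

NEG_INF = float("-inf")


@dataclass
class FitnessRecord:
    """Outcome of evaluating one individual once."""

    individual_id: int
    fitness_vector: np.ndarray
    scalar_fitness: float
    seed: int
    failed: bool = False

    def __post_init__(self):
        self.fitness_vector = np.asarray(self.fitness_vector, dtype=float)

    def __eq__(self, other):
        if not isinstance(other, FitnessRecord):
            return NotImplemented
        return (
            self.individual_id == other.individual_id
            and np.array_equal(self.fitness_vector, other.fitness_vector, equal_nan=True)
            and (self.scalar_fitness == other.scalar_fitness
                 or (np.isnan(self.scalar_fitness) and np.isnan(other.scalar_fitness)))
            and self.seed == other.seed
            and self.failed == other.failed
        )


@dataclass
class GenerationRecord:
    individuals: list[Individual]
    records: list[FitnessRecord]

    def __post_init__(self):
        if len(self.individuals) != len(self.records):
            raise ContractError("one fitness record per individual is required")

    def __eq__(self, other):
        if not isinstance(other, GenerationRecord):
            return NotImplemented
        return self.individuals == other.individuals and self.records == other.records

    @property
    def best(self) -> tuple[Individual, FitnessRecord]:
        i = int(np.argmax([r.scalar_fitness for r in self.records]))
        return self.individuals[i], self.records[i]


@dataclass
class Trajectory:
    """Append-only, generation-indexed run history."""

    config: dict = field(default_factory=dict)
    seed: int = 0
    generations: list[GenerationRecord] = field(default_factory=list)

    def append(self, individuals: list[Individual], records: list[FitnessRecord]) -> None:
        n_pop = self.config.get("n_pop")
        if n_pop is not None and len(individuals) != n_pop:
            raise ContractError(
                f"generation has {len(individuals)} individuals, population size is {n_pop}"
            )
        self.generations.append(GenerationRecord(list(individuals), list(records)))

    def __len__(self) -> int:
        return len(self.generations)

    def __eq__(self, other):
        if not isinstance(other, Trajectory):
            return NotImplemented
        return (
            self.config == other.config
            and self.seed == other.seed
            and self.generations == other.generations
        )

    # -- summaries -----------------------------------------------------------

    def best_per_generation(self) -> np.ndarray:
        return np.array([g.best[1].scalar_fitness for g in self.generations])

    def best_ever(self) -> tuple[Individual, FitnessRecord]:
        best_ind, best_rec = None, None
        for g in self.generations:
            ind, rec = g.best
            if best_rec is None or rec.scalar_fitness > best_rec.scalar_fitness:
                best_ind, best_rec = ind, rec
        if best_rec is None:
            raise ContractError("empty trajectory has no best individual")
        return best_ind, best_rec

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (generation, individual)."""
        rows = []
        for g, gen in enumerate(self.generations):
            for ind, rec in zip(gen.individuals, gen.records):
                row = {"generation": g, "individual_id": rec.individual_id,
                       "scalar_fitness": rec.scalar_fitness, "seed": rec.seed,
                       "failed": rec.failed}
                for j, f in enumerate(rec.fitness_vector):
                    row[f"fitness_{j}"] = f
                for name, v in ind.values.items():
                    v = np.atleast_1d(v)
                    if v.size == 1:
                        row[name] = float(v[0])
                    else:
                        for j, x in enumerate(v):
                            row[f"{name}_{j}"] = float(x)
                rows.append(row)
        return pd.DataFrame(rows)

    def export_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# persistence


def persist_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory to a self-describing HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "metaloop-trajectory"
        f.attrs["version"] = 1
        f.attrs["config"] = json.dumps(traj.config)
        f.attrs["seed"] = traj.seed
        f.attrs["n_generations"] = len(traj.generations)
        for g, gen in enumerate(traj.generations):
            grp = f.create_group(f"generations/{g:06d}")
            grp.create_dataset(
                "individual_id", data=np.array([r.individual_id for r in gen.records]),
                track_times=False)
            grp.create_dataset(
                "generation_index", data=np.array([i.generation for i in gen.individuals]),
                track_times=False)
            grp.create_dataset(
                "fitness_vector", data=np.array([r.fitness_vector for r in gen.records]),
                track_times=False)
            grp.create_dataset(
                "scalar_fitness", data=np.array([r.scalar_fitness for r in gen.records]),
                track_times=False)
            grp.create_dataset(
                "eval_seed", data=np.array([r.seed for r in gen.records]),
                track_times=False)
            grp.create_dataset(
                "failed", data=np.array([r.failed for r in gen.records]),
                track_times=False)
            pgrp = grp.create_group("parameters")
            names = list(gen.individuals[0].values) if gen.individuals else []
            pgrp.attrs["names"] = json.dumps(names)
            for name in names:
                pgrp.create_dataset(
                    name, data=np.array([np.atleast_1d(i.values[name]) for i in gen.individuals]),
                    track_times=False)


def load_trajectory(path) -> Trajectory:
    """Read a trajectory back; exact inverse of :func:`persist_trajectory`."""
    try:
        f = h5py.File(path, "r")
    except OSError as e:
        raise TrajectoryLoadError(f"cannot open trajectory file {path}: {e}") from e
    with f:
        try:
            config = json.loads(f.attrs["config"])
            seed = int(f.attrs["seed"])
            n_gen = int(f.attrs["n_generations"])
        except (KeyError, json.JSONDecodeError) as e:
            raise TrajectoryLoadError(f"corrupt trajectory header in {path}: {e}") from e
        traj = Trajectory(config=config, seed=seed)
        for g in range(n_gen):
            try:
                grp = f[f"generations/{g:06d}"]
                ids = grp["individual_id"][()]
                gen_idx = grp["generation_index"][()]
                fv = grp["fitness_vector"][()]
                sf = grp["scalar_fitness"][()]
                ev_seed = grp["eval_seed"][()]
                failed = grp["failed"][()]
                names = json.loads(grp["parameters"].attrs["names"])
                params = {name: grp[f"parameters/{name}"][()] for name in names}
            except (KeyError, OSError) as e:
                raise TrajectoryLoadError(
                    f"corrupt trajectory record in {path}", generation=g) from e
            individuals, records = [], []
            for i in range(len(ids)):
                individuals.append(Individual(
                    values={name: params[name][i].copy() for name in names},
                    id=int(ids[i]), generation=int(gen_idx[i])))
                records.append(FitnessRecord(
                    individual_id=int(ids[i]), fitness_vector=fv[i],
                    scalar_fitness=float(sf[i]), seed=int(ev_seed[i]),
                    failed=bool(failed[i])))
            traj.generations.append(GenerationRecord(individuals, records))
    return traj
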
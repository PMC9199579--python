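"""Two-loop orchestration: scalarization, parallel evaluation, trajectory
persistence, and the full run loop."""

import numpy as np
import pytest

from metaloop.errors import (ConfigurationError, ContractError,
                             EvaluationError, TrajectoryLoadError)
from metaloop.evaluation import (Optimizee, evaluate_generation,
                                 individual_seed, weighted_fitness)
from metaloop.experiment import ExperimentConfig, make_optimizee, run_experiment
from metaloop.parameters import Individual, ParameterEntry, ParameterSpec
from metaloop.trajectory import (FitnessRecord, Trajectory, load_trajectory,
                                 persist_trajectory)
from metaloop.testbeds.benchmarks import BenchmarkOptimizee


class TestWeightedFitness:
    @pytest.mark.parametrize("fv, w, expected", [
        ((2.0, 4.0), (1.0, 0.5), 4.0),
        ((3.5,), (1.0,), 3.5),
        ((2.0, 4.0), (0.0, 0.0), 0.0),
    ])
    def test_dot_product(self, fv, w, expected):
        assert weighted_fitness(fv, w) == expected

    def test_length_mismatch(self):
        with pytest.raises(ContractError):
            weighted_fitness((1.0, 2.0), (1.0,))


class FailingOptimizee(Optimizee):
    """Sphere surface, but individual id 3 always raises."""

    def __init__(self, always_fail=False):
        self.always_fail = always_fail

    def parameter_spec(self):
        return ParameterSpec((ParameterEntry("x", 2, -5.0, 5.0),))

    def simulate(self, individual, rng):
        if self.always_fail or individual.id == 3:
            raise RuntimeError("simulated crash")
        return np.array([-np.sum(individual.values["x"] ** 2)])


class TestEvaluateGeneration:
    def _population(self, optimizee, n, seed=0):
        rng = np.random.default_rng(seed)
        return [optimizee.create_individual(rng, id=i) for i in range(n)]

    def test_serial_equals_parallel(self):
        opt = BenchmarkOptimizee("sphere", 3)
        pop = self._population(opt, 8)
        serial = evaluate_generation(pop, opt, experiment_seed=5, n_workers=1)
        parallel = evaluate_generation(pop, opt, experiment_seed=5, n_workers=4)
        assert serial == parallel

    def test_population_of_98_yields_98_records(self):
        opt = BenchmarkOptimizee("sphere", 1)
        pop = self._population(opt, 98)
        records = evaluate_generation(pop, opt)
        assert len(records) == 98
        assert [r.individual_id for r in records] == list(range(98))

    def test_failure_isolated_with_neg_inf(self):
        opt = FailingOptimizee()
        pop = self._population(opt, 6)
        records = evaluate_generation(pop, opt)
        assert records[3].failed and records[3].scalar_fitness == -np.inf
        assert all(not r.failed for i, r in enumerate(records) if i != 3)

    def test_all_failed_aborts(self):
        opt = FailingOptimizee(always_fail=True)
        with pytest.raises(EvaluationError):
            evaluate_generation(self._population(opt, 4), opt)

    def test_individual_seed_is_stable_and_bounded(self):
        s = individual_seed(1, 2, 3)
        assert s == individual_seed(1, 2, 3)
        assert 0 <= s < 2**31
        assert s != individual_seed(1, 2, 4)


class TestTrajectoryPersistence:
    def _trajectory(self, n_gen=3, n_pop=4):
        rng = np.random.default_rng(0)
        traj = Trajectory(config={"n_pop": n_pop, "name": "t"}, seed=7)
        for g in range(n_gen):
            individuals = [Individual(values={"x": rng.normal(size=2)},
                                      id=i, generation=g) for i in range(n_pop)]
            records = [FitnessRecord(individual_id=i,
                                     fitness_vector=rng.normal(size=2),
                                     scalar_fitness=float(rng.normal()),
                                     seed=int(rng.integers(1 << 30)))
                       for i in range(n_pop)]
            traj.append(individuals, records)
        return traj

    def test_round_trip_equality(self, tmp_path):
        traj = self._trajectory()
        path = tmp_path / "t.h5"
        persist_trajectory(traj, path)
        assert load_trajectory(path) == traj

    def test_empty_trajectory_round_trips(self, tmp_path):
        traj = Trajectory(config={"name": "empty"}, seed=1)
        persist_trajectory(traj, tmp_path / "e.h5")
        assert load_trajectory(tmp_path / "e.h5") == traj

    def test_fitness_row_count_on_disk(self, tmp_path):
        traj = self._trajectory(n_gen=3, n_pop=4)
        frame = traj.to_frame()
        assert len(frame) == 12
        traj.export_csv(tmp_path / "t.csv")
        import pandas as pd
        assert len(pd.read_csv(tmp_path / "t.csv")) == 12

    def test_corrupt_file_names_failing_generation(self, tmp_path):
        import h5py
        path = tmp_path / "c.h5"
        persist_trajectory(self._trajectory(), path)
        with h5py.File(path, "a") as f:
            del f["generations/000001/scalar_fitness"]
        with pytest.raises(TrajectoryLoadError) as err:
            load_trajectory(path)
        assert err.value.generation == 1


class TestRunExperiment:
    def test_grid_search_finds_quadratic_optimum(self):
        """Grid of 101 points on [0, 1] vs f(x) = -(x - 0.3)^2: exhaustive
        evaluation must return exactly the dense-grid argmax, x = 0.3."""
        config = ExperimentConfig(
            optimizee_name="quadratic", optimizer_name="grid-search",
            optimizer_params={"resolution": 101}, n_pop=1, n_generations=5)
        from metaloop.experiment import OPTIMIZEES

        class Quadratic(Optimizee):
            def parameter_spec(self):
                return ParameterSpec((ParameterEntry("x", 1, 0.0, 1.0),))

            def simulate(self, individual, rng):
                return np.array([-(individual.values["x"][0] - 0.3) ** 2])

        OPTIMIZEES["quadratic"] = lambda params: Quadratic()
        try:
            traj = run_experiment(config)
        finally:
            del OPTIMIZEES["quadratic"]
        assert len(traj) == 1  # one-shot optimizer
        best_ind, best_rec = traj.best_ever()
        assert best_ind.values["x"][0] == pytest.approx(0.3, abs=1e-12)
        assert best_rec.scalar_fitness == pytest.approx(0.0, abs=1e-12)

    def test_ga_best_ever_non_decreasing(self):
        config = ExperimentConfig(
            optimizee_name="sphere", optimizer_name="genetic-algorithm",
            optimizee_params={"dimension": 2}, n_pop=20, n_generations=50,
            seed=3)
        traj = run_experiment(config)
        best = traj.best_per_generation()
        running = np.maximum.accumulate(best)
        assert running[-1] >= running[0]
        # Hall-of-Fame property: the running best never decreases
        assert np.all(np.diff(running) >= 0)

    def test_reproducible_given_config_and_seed(self, tmp_path):
        def run(outdir):
            config = ExperimentConfig(
                optimizee_name="sphere", optimizer_name="evolution-strategies",
                optimizee_params={"dimension": 2}, n_pop=8, n_generations=5,
                seed=11, results_path=str(outdir), name="rep")
            return run_experiment(config)

        t1 = run(tmp_path / "a")
        t2 = run(tmp_path / "b")
        assert t1 == t2
        assert (tmp_path / "a" / "rep.h5").exists()
        assert load_trajectory(tmp_path / "a" / "rep.h5") == t1

    def test_unknown_names_list_registered(self):
        with pytest.raises(ConfigurationError, match="registered optimizees"):
            make_optimizee("nope")
        config = ExperimentConfig(optimizee_name="sphere",
                                  optimizer_name="nope")
        with pytest.raises(ConfigurationError, match="registered optimizers"):
            run_experiment(config)

    def test_bounds_enforced_after_every_step(self):
        config = ExperimentConfig(
            optimizee_name="sphere", optimizer_name="genetic-algorithm",
            optimizee_params={"dimension": 2, "low": -1.0, "high": 1.0},
            optimizer_params={"mutation_sigma": 5.0, "mutation_prob": 1.0},
            n_pop=12, n_generations=8, seed=0)
        traj = run_experiment(config)
        for gen in traj.generations:
            for ind in gen.individuals:
                x = ind.values["x"]
                assert x.min() >= -1.0 and x.max() <= 1.0

    def test_population_size_conserved(self):
        config = ExperimentConfig(
            optimizee_name="sphere", optimizer_name="cross-entropy",
            optimizee_params={"dimension": 2}, n_pop=10, n_generations=6)
        traj = run_experiment(config)
        assert all(len(g.individuals) == 10 for g in traj.generations)


class TestConfigFromYaml:
    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "run.yaml"
        path.write_text("""
experiment:
  name: demo
  seed: 9
  n_generations: 4
  population: 6
  weights: [1.0, 0.5]
  workers: 2
optimizee:
  name: sphere
  params: {dimension: 3}
optimizer:
  name: genetic-algorithm
  params: {tournament_size: 2}
""")
        config = ExperimentConfig.from_yaml(path)
        assert config.name == "demo"
        assert config.seed == 9
        assert config.weights == (1.0, 0.5)
        assert config.optimizee_params == {"dimension": 3}
        assert config.optimizer_params == {"tournament_size": 2}

    def test_missing_names_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("experiment: {seed: 1}\noptimizee: {name: sphere}\n"
                        "optimizer: {}\n")
        with pytest.raises(ConfigurationError):
            ExperimentConfig.from_yaml(path)
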
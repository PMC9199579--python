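"""Environments, surrogate models and synthetic-data generators."""

import numpy as np
import pytest

from metaloop.errors import ConfigurationError, ContractError
from metaloop.fitness import mc_fitness
from metaloop.testbeds.benchmarks import BenchmarkOptimizee, benchmark_function
from metaloop.testbeds.digits import (nearest_centroid_accuracy,
                                      synthetic_digits)
from metaloop.testbeds.mountain_car import (MCPolicyRunner, MCState, mc_reset,
                                            mc_step, run_mc_episode)
from metaloop.testbeds.oscillator import (fc_fitness_batch, modular_sc,
                                          oscillator_network)
from metaloop.testbeds.toy_cell import (StimulusClamp, ToyCellParams,
                                        toy_cell_trace)
from metaloop.fitness import fc_sc_fitness


class TestMountainCarDynamics:
    def test_single_step_hand_computed(self):
        """Right push from (-0.5, 0): v = 0.001 - 0.0025 cos(-1.5)."""
        state, done = mc_step(MCState(-0.5, 0.0), 2)
        expected_v = 0.001 - 0.0025 * np.cos(-1.5)
        assert state.velocity == pytest.approx(expected_v, abs=1e-12)
        assert state.position == pytest.approx(-0.5 + expected_v, abs=1e-12)
        assert not done

    def test_done_exactly_at_goal(self):
        state, done = mc_step(MCState(0.499, 0.07), 2)
        assert done and state.position >= 0.5
        _, not_done = mc_step(MCState(0.3, 0.0), 1)
        assert not not_done

    def test_bounds_never_exceeded_on_random_rollouts(self):
        rng = np.random.default_rng(0)
        state = mc_reset(rng)
        for _ in range(500):
            state, done = mc_step(state, int(rng.integers(0, 3)))
            assert -1.2 <= state.position <= 0.6
            assert -0.07 <= state.velocity <= 0.07
            if done:
                state = mc_reset(rng)

    def test_reset_near_valley(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            s = mc_reset(rng)
            assert -0.6 <= s.position <= -0.4 and s.velocity == 0.0


class TestMCPolicyEpisodes:
    def test_dead_network_never_reaches_goal(self):
        trace, reached = run_mc_episode(np.zeros(315), max_steps=110,
                                        rng=np.random.default_rng(0))
        assert reached is None
        assert trace.shape == (110,)
        assert mc_fitness(trace) < 0.5

    def test_fitness_composition(self):
        """mc_fitness over the episode trace is 0.5 exactly when the goal
        was reached (position is clamped below the summit otherwise)."""
        trace, reached = run_mc_episode(np.zeros(315), max_steps=50,
                                        rng=np.random.default_rng(1))
        assert (reached is not None) == (mc_fitness(trace) >= 0.5)

    def test_batched_rollout_matches_per_episode_runs(self):
        rng = np.random.default_rng(3)
        w = rng.uniform(-20, 20, 315)
        starts = [mc_reset(np.random.default_rng(s)) for s in (1, 2)]
        batched = MCPolicyRunner(w, batch=2, dt=0.4)
        traces, steps = batched.rollout(starts, 40)
        for i, start in enumerate(starts):
            single = MCPolicyRunner(w, batch=1, dt=0.4)
            t1, s1 = single.rollout([MCState(start.position, start.velocity)], 40)
            np.testing.assert_allclose(t1[0], traces[i], atol=1e-12)

    def test_compiled_rollout_identical_to_reference_engine(self):
        """The fused JIT rollout reproduces the vectorized numpy engine
        bit for bit (same update order, same episodes)."""
        rng = np.random.default_rng(11)
        w = rng.uniform(-20, 20, (4, 315))
        starts = [mc_reset(np.random.default_rng(s)) for s in range(4)]
        copies = [MCState(s.position, s.velocity) for s in starts]
        tk, sk = MCPolicyRunner(w, dt=0.2, use_kernel=True).rollout(starts, 60)
        tn, sn = MCPolicyRunner(w, dt=0.2, use_kernel=False).rollout(copies, 60)
        np.testing.assert_array_equal(tk, tn)
        np.testing.assert_array_equal(sk, sn)


class TestToyCell:
    def test_zero_amplitude_rests_at_leak_reversal(self):
        trace = toy_cell_trace(ToyCellParams(),
                               StimulusClamp(amplitude=0.0), 100.0, 0.1)
        np.testing.assert_allclose(trace.samples, -70.0, atol=1e-9)

    def test_spike_count_monotone_in_amplitude(self):
        counts = []
        for amp in [0.8, 1.1, 1.5, 2.0, 3.0]:
            trace = toy_cell_trace(ToyCellParams(),
                                   StimulusClamp(amplitude=amp), 300.0, 0.1)
            counts.append(int((trace.samples == 20.0).sum()))
        assert counts == sorted(counts)
        assert counts[0] == 0 and counts[-1] > 0  # sub- vs supra-rheobase

    def test_bitwise_deterministic(self):
        a = toy_cell_trace(ToyCellParams(), StimulusClamp(), 200.0, 0.1)
        b = toy_cell_trace(ToyCellParams(), StimulusClamp(), 200.0, 0.1)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_unstable_dt_refused(self):
        with pytest.raises(ConfigurationError), pytest.warns(UserWarning):
            toy_cell_trace(ToyCellParams(), StimulusClamp(), 100.0, dt=50.0)

    def test_trace_csv_round_trip(self, tmp_path):
        trace = toy_cell_trace(ToyCellParams(), StimulusClamp(), 100.0, 0.1)
        trace.to_csv(tmp_path / "ref.csv")
        from metaloop.fitness import VoltageTrace
        loaded = VoltageTrace.from_csv(tmp_path / "ref.csv")
        np.testing.assert_allclose(loaded.samples, trace.samples)
        assert loaded.dt == pytest.approx(trace.dt)


class TestOscillator:
    def test_output_shape(self):
        SC = modular_sc(6, rng=np.random.default_rng(0))
        series = oscillator_network(SC, 0.3, 2.0, steps=200)
        assert series.shape == (6, 200)

    def test_uncoupled_fc_is_weak(self):
        """With coupling 0 the oscillators are independent: mean
        off-diagonal |FC| stays small."""
        SC = modular_sc(8, rng=np.random.default_rng(1))
        series = oscillator_network(SC, 0.0, 2.0, steps=800,
                                    rng=np.random.default_rng(2))
        FC = np.corrcoef(series[:, 200:])
        off = np.abs(FC[np.triu_indices(8, 1)])
        assert off.mean() < 0.2

    def test_fitness_rises_with_coupling_in_weak_regime(self):
        """Across seeds, the FC-SC fitness trend over increasing coupling
        is positive below the synchronization peak."""
        slopes = []
        for seed in range(10):
            SC = modular_sc(10, rng=np.random.default_rng(seed))
            couplings = np.array([0.05, 0.2, 0.35, 0.5])
            f = fc_fitness_batch(
                SC, np.stack([couplings, np.full(4, 2.0)], axis=1),
                steps=400, noise_seed=seed)
            slopes.append(np.polyfit(couplings, f, 1)[0])
        assert np.mean(slopes) > 0
        assert sum(s > 0 for s in slopes) >= 8

    def test_common_noise_makes_fitness_deterministic(self):
        SC = modular_sc(6, rng=np.random.default_rng(3))
        p = np.array([[0.3, 2.0]])
        f1 = fc_fitness_batch(SC, p, steps=300)
        f2 = fc_fitness_batch(SC, p, steps=300)
        assert f1[0] == f2[0]


class TestSyntheticDigits:
    def test_balanced_labels_and_range(self):
        x, y = synthetic_digits(7, rng=np.random.default_rng(0))
        assert x.shape == (21, 768)
        assert [int((y == c).sum()) for c in range(3)] == [7, 7, 7]
        assert x.min() >= 0 and x.max() <= 255

    def test_separability_guarantee(self):
        x, y = synthetic_digits(20, noise=0.1, rng=np.random.default_rng(1))
        assert nearest_centroid_accuracy(x, y) >= 0.95

    def test_deterministic_given_seed(self):
        x1, y1 = synthetic_digits(5, rng=np.random.default_rng(9))
        x2, y2 = synthetic_digits(5, rng=np.random.default_rng(9))
        np.testing.assert_array_equal(x1, x2)
        np.testing.assert_array_equal(y1, y2)

    def test_too_few_classes_rejected(self):
        with pytest.raises(ConfigurationError):
            synthetic_digits(5, n_classes=1)


class TestBenchmarks:
    def test_optima_and_hand_values(self):
        assert benchmark_function("sphere", [0.0, 0.0]) == 0.0
        assert benchmark_function("rastrigin", [0.0, 0.0]) == 0.0
        assert benchmark_function("sphere", [1.0, 1.0]) == -2.0

    def test_unknown_name(self):
        with pytest.raises(ConfigurationError):
            benchmark_function("banana", [0.0])

    def test_optimizee_wraps_function(self):
        opt = BenchmarkOptimizee("sphere", 3)
        ind = opt.create_individual(np.random.default_rng(0))
        fv = opt.simulate(ind, np.random.default_rng(0))
        assert fv.shape == (1,)
        assert fv[0] == benchmark_function("sphere", ind.values["x"])
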
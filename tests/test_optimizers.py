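"""Outer-loop optimizer algebra: oracle equivalences, convergence, and the
degenerate-input conventions."""

import numpy as np
import pytest

from metaloop.errors import ConfigurationError, ContractError
from metaloop.parameters import ParameterEntry, ParameterSpec
from metaloop.optimizers import (CEConfig, ESConfig, GAConfig, GDConfig,
                                 HallOfFame, SAConfig, ce_step, cooling,
                                 enkf_update, es_step, ga_step,
                                 gradient_step, grid_generate,
                                 multi_gradient_step, rank_replace_perturb,
                                 sa_accept)
from metaloop.optimizers.gradient import estimate_gradient


class TestEnKF:
    def test_zero_spread_ensemble_unchanged(self):
        ens = np.full((4, 3), 0.5)
        preds = np.full((4, 2), 0.1)
        out = enkf_update(ens, preds, np.array([1.0, 1.0]), 0.5)
        np.testing.assert_allclose(out, ens, atol=1e-14)

    def test_scalar_identity_model_hand_example(self):
        """g(u) = u, ensemble {0, 1}, target 1, gamma 1: C_dd = 0.25 and
        u <- u + 0.2 (1 - u), i.e. {0.2, 1.0}."""
        ens = np.array([[0.0], [1.0]])
        out = enkf_update(ens, ens.copy(), np.array([1.0]), 1.0)
        np.testing.assert_allclose(out.ravel(), [0.2, 1.0], atol=1e-12)

    def test_matches_closed_form_regularized_kalman(self):
        """Linear-Gaussian scalar oracle: for g(u) = a u the update must
        equal u + C_ud (C_dd + gamma)^(-1) (y - a u) computed by hand."""
        rng = np.random.default_rng(0)
        u = rng.normal(size=(12, 1))
        a, gamma, y = 1.7, 0.5, 2.0
        preds = a * u
        du = u - u.mean()
        C_uu = float((du * du).mean())
        C_ud, C_dd = a * C_uu, a * a * C_uu
        expected = u + C_ud / (C_dd + gamma) * (y - preds)
        out = enkf_update(u, preds, np.array([y]), gamma)
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_huge_gamma_freezes_ensemble(self):
        rng = np.random.default_rng(1)
        ens = rng.random((6, 4))
        preds = rng.random((6, 3))
        out = enkf_update(ens, preds, np.ones(3), 1e9)
        np.testing.assert_allclose(out, ens, atol=1e-6)

    def test_too_small_ensemble_rejected(self):
        with pytest.raises(ContractError):
            enkf_update(np.ones((1, 2)), np.ones((1, 1)), np.ones(1), 0.5)


class TestRankReplacePerturb:
    def test_single_worst_becomes_copy_of_best(self):
        rng = np.random.default_rng(0)
        ens = np.arange(10.0)[:, None]
        fit = np.arange(10.0)  # member 9 best, member 0 worst
        out = rank_replace_perturb(ens, fit, 0.1, 0.0, rng)
        assert out[0, 0] == 9.0
        np.testing.assert_array_equal(out[1:], ens[1:])

    def test_ten_percent_of_98_replaces_9(self):
        rng = np.random.default_rng(0)
        ens = np.arange(98.0)[:, None]
        out = rank_replace_perturb(ens, np.arange(98.0), 0.1, 0.0, rng)
        changed = (out != ens).sum()
        assert changed == 9
        # rank-to-rank pairing: worst gets best, 2nd-worst 2nd-best, ...
        np.testing.assert_array_equal(out[:9, 0], np.arange(97, 88, -1))

    def test_zero_fraction_identity(self):
        rng = np.random.default_rng(0)
        ens = np.random.default_rng(1).random((5, 2))
        np.testing.assert_array_equal(
            rank_replace_perturb(ens, np.arange(5.0), 0.0, 1.0, rng), ens)


class TestGA:
    def test_selection_only_converges_to_best(self):
        """With crossover and mutation off, repeated tournament selection on
        a fixed 5-member population drives everyone onto the best member
        (brute-force expectation of selection-only dynamics)."""
        rng = np.random.default_rng(0)
        pop = np.arange(5.0)[:, None]
        config = GAConfig(crossover_prob=0.0, mutation_prob=0.0,
                          tournament_size=3)
        hof = HallOfFame(1)
        for _ in range(30):
            fit = pop[:, 0]  # fitness = the value itself
            pop = ga_step(pop, fit, config, hof, rng)
        assert np.all(pop == 4.0)
        assert hof.best_fitness == 4.0

    def test_hof_monotone_and_tie_keeps_first(self):
        hof = HallOfFame(1)
        hof.update(np.array([[1.0]]), np.array([0.5]))
        first = hof.best_vector.copy()
        hof.update(np.array([[2.0]]), np.array([0.5]))  # tie: keep first
        assert hof.best_vector[0] == first[0]
        hof.update(np.array([[3.0]]), np.array([0.7]))
        assert hof.best_fitness == 0.7

    def test_sphere_convergence_with_printed_config(self):
        """Population 100, 200 generations on the 2-d sphere: the best
        solution ends within 1e-2 of the optimum."""
        rng = np.random.default_rng(5)
        pop = rng.uniform(-5, 5, (100, 2))
        config = GAConfig(mutation_sigma=0.3)
        hof = HallOfFame(1)
        for _ in range(200):
            fit = -np.sum(pop**2, axis=1)
            pop = ga_step(pop, fit, config, hof, rng)
            pop = np.clip(pop, -5, 5)
        assert hof.best_fitness >= -1e-2


class TestES:
    def test_no_signal_no_movement(self):
        center = np.array([1.0, -2.0])
        noises = np.random.default_rng(0).normal(size=(8, 2))
        out = es_step(center, np.full(8, 3.3), noises, ESConfig())
        np.testing.assert_allclose(out, center, atol=1e-12)

    def test_expected_step_direction_downhill(self):
        """1-d f(x) = -x^2 around center 1: the update moves left in the
        vast majority of resamples (Monte-Carlo sign test)."""
        config = ESConfig(sigma=0.1, learning_rate=0.5, n_offspring=20)
        rng = np.random.default_rng(7)
        center = np.array([1.0])
        moves_left = 0
        for _ in range(300):
            eps = rng.normal(size=(20, 1))
            fit = -((center + config.sigma * eps.ravel()) ** 2)
            moves_left += es_step(center, fit, eps, config)[0] < center[0]
        assert moves_left > 270

    def test_mirrored_pairs_recover_linear_gradient_sign(self):
        """Mirrored +-eps with a linear fitness: utilities cancel pairwise
        into a step exactly along the slope direction (1-d)."""
        config = ESConfig(sigma=0.5, learning_rate=1.0, n_offspring=6)
        eps = np.array([[0.3], [-0.3], [1.0], [-1.0], [0.2], [-0.2]])
        fit = 2.0 * eps.ravel()  # linear, increasing
        out = es_step(np.array([0.0]), fit, eps, config)
        assert out[0] > 0
        out_neg = es_step(np.array([0.0]), -fit, eps, config)
        assert out_neg[0] == pytest.approx(-out[0], abs=1e-12)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ConfigurationError):
            ESConfig(sigma=0.0)


class TestGradient:
    def test_linear_fitness_recovers_slope_exactly(self):
        rng = np.random.default_rng(0)
        a = np.array([2.0, -1.0, 0.5])
        offsets = rng.normal(size=(12, 3))
        g = estimate_gradient(offsets, offsets @ a + 7.0)
        np.testing.assert_allclose(g, a, atol=1e-10)

    def test_zero_learning_rate_no_move(self):
        center = np.array([1.0, 2.0])
        probes = center + np.random.default_rng(0).normal(size=(6, 2))
        out = gradient_step(center, probes, np.arange(6.0),
                            GDConfig(learning_rate=0.0))
        np.testing.assert_array_equal(out, center)

    def test_quadratic_bowl_distance_shrinks_in_expectation(self):
        config = GDConfig(learning_rate=0.05, probe_scale=0.2)
        rng = np.random.default_rng(3)
        dists = []
        for _ in range(20):
            center = np.array([2.0, -2.0])
            for _ in range(200):
                probes = center + config.probe_scale * rng.normal(size=(8, 2))
                fit = -np.sum(probes**2, axis=1)
                center = gradient_step(center, probes, fit, config)
            dists.append(np.linalg.norm(center))
        assert np.mean(dists) < 1.0


class TestMultiGradient:
    def test_dominant_combination_becomes_center(self):
        clouds = np.zeros((1, 5, 2))
        clouds[0, 3] = [0.7, 0.2]
        fv = np.array([[0.0, 0.0, 0.0, 10.0, 0.0]])
        new_clouds, _ = multi_gradient_step(
            clouds, fv, GDConfig(learning_rate=0.0, mode="multi"),
            np.array([[0.1, 0.1]]))
        np.testing.assert_allclose(new_clouds[0].mean(axis=0), [0.7, 0.2],
                                   atol=1e-9)

    def test_expand_compress_counts(self):
        """4 individuals x 1024 combinations expand to 4096 fitnesses and
        compress back to 4096 fresh combinations."""
        rng = np.random.default_rng(0)
        clouds = rng.random((4, 1024, 2))
        fv = rng.random((4, 1024))
        new_clouds, _ = multi_gradient_step(
            clouds, fv, GDConfig(mode="multi"), np.full((4, 2), 0.5))
        assert fv.size == 4096
        assert new_clouds.reshape(-1, 2).shape == (4096, 2)

    def test_concave_fitness_matches_grid_oracle(self):
        """30 shrink-and-recenter steps on a smooth 2-d concave surface end
        within 1% of the dense-grid optimum."""
        def f(xy):
            return -(xy[:, 0] - 0.3) ** 2 - 2 * (xy[:, 1] + 0.4) ** 2

        grid = np.stack(np.meshgrid(np.linspace(-1, 1, 200),
                                    np.linspace(-1, 1, 200), indexing="ij"),
                        -1).reshape(-1, 2)
        oracle = f(grid).max()

        config = GDConfig(learning_rate=0.01, mode="multi")
        half = np.full((2, 2), 1.0)
        rng = np.random.default_rng(1)
        centers = rng.uniform(-1, 1, (2, 2))
        from metaloop.optimizers.gradient import _cloud_grid
        clouds = np.stack([_cloud_grid(c, h, 64) for c, h in zip(centers, half)])
        best = -np.inf
        for _ in range(30):
            fv = f(clouds.reshape(-1, 2)).reshape(2, 64)
            best = max(best, fv.max())
            clouds, half = multi_gradient_step(clouds, fv, config, half)
        assert best >= oracle - 0.01 * abs(oracle) - 1e-6

    def test_empty_cloud_rejected(self):
        with pytest.raises(ContractError):
            multi_gradient_step(np.zeros((1, 0, 2)), np.zeros((1, 0)),
                                GDConfig(mode="multi"), np.ones((1, 2)))


class TestSimulatedAnnealing:
    def test_improvements_always_accepted(self):
        rng = np.random.default_rng(0)
        assert all(sa_accept(0.5, t, rng) for t in (0.01, 1.0, 100.0))

    def test_greedy_limit(self):
        rng = np.random.default_rng(0)
        assert not any(sa_accept(-1.0, 1e-9, rng) for _ in range(100))

    def test_acceptance_rate_matches_boltzmann(self):
        """delta f = -1 at T = 1 accepts with probability e^-1 ~ 0.368."""
        rng = np.random.default_rng(123)
        rate = np.mean([sa_accept(-1.0, 1.0, rng) for _ in range(10_000)])
        assert rate == pytest.approx(np.exp(-1), abs=0.015)

    def test_cooling_schedules(self):
        config = SAConfig(initial_temperature=2.0, cooling_factor=0.9)
        assert cooling("exponential", 0, config) == 2.0
        assert cooling("exponential", 3, config) == pytest.approx(2.0 * 0.9**3)
        assert cooling("linear", 5, config) == pytest.approx(2.0 * 0.5)
        assert cooling("logarithmic", 0, config) == pytest.approx(2.0)
        for kind in ("exponential", "linear", "logarithmic"):
            assert cooling(kind, 10_000, config) > 0

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ConfigurationError):
            SAConfig(initial_temperature=0.0)


class TestCrossEntropy:
    def test_degenerate_elites_concentrate(self):
        rng = np.random.default_rng(0)
        pop = np.vstack([np.full((2, 2), 3.0),
                         np.random.default_rng(1).normal(size=(8, 2))])
        fit = np.array([10.0, 10.0] + [0.0] * 8)
        mean, var, new_pop = ce_step(pop, fit, CEConfig(elite_fraction=0.2), rng)
        np.testing.assert_allclose(mean, [3.0, 3.0], atol=1e-12)
        assert np.all(var <= 1e-10)  # floored, not zero
        assert np.abs(new_pop - 3.0).max() < 1e-4

    def test_elite_fraction_one_refits_population_moments(self):
        rng = np.random.default_rng(0)
        pop = np.random.default_rng(2).normal(size=(50, 3))
        mean, var, _ = ce_step(pop, np.zeros(50), CEConfig(elite_fraction=1.0),
                               rng)
        np.testing.assert_allclose(mean, pop.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(var, pop.var(axis=0), atol=1e-12)

    def test_one_d_bowl_converges(self):
        rng = np.random.default_rng(4)
        pop = rng.uniform(-5, 5, (40, 1))
        mean = var = None
        config = CEConfig(elite_fraction=0.25, smoothing=0.8)
        for _ in range(30):
            fit = -((pop[:, 0] - 1.5) ** 2)
            mean, var, pop = ce_step(pop, fit, config, rng, mean, var)
        assert mean[0] == pytest.approx(1.5, abs=0.01)


class TestGridSearch:
    def test_endpoints_included(self, scalar_spec):
        pop = grid_generate(scalar_spec, 3)
        vals = sorted(ind.values["x"][0] for ind in pop)
        assert vals == [0.0, 0.5, 1.0]

    def test_two_parameter_combination_count(self):
        spec = ParameterSpec((ParameterEntry("a", 1, 0, 1),
                              ParameterEntry("b", 1, 0, 1)))
        assert len(grid_generate(spec, 20)) == 400

    def test_cap_error_cites_the_power(self):
        spec = ParameterSpec((ParameterEntry("w", 500, -20, 20),))
        with pytest.raises(ConfigurationError, match=r"20\^500"):
            grid_generate(spec, 20)
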
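import numpy as np
import pytest

from elicitopt.ga import (DEFAULT_BOUNDS, GAConfig, VariableBounds,
                          ga_maximize, init_population, optimize_model,
                          roulette_select, two_point_crossover,
                          uniform_mutation, _selection_probs)

BOX2 = VariableBounds(("x1", "x2"), (0.0, 0.0), (10.0, 10.0))


class FixedCutRng:
    """Stub RNG forcing a crossover with prescribed cut points."""

    def __init__(self, cuts):
        self.cuts = np.array(cuts)

    def random(self, *a):
        return 0.0  # always below the crossover rate

    def choice(self, values, size=None, replace=True):
        return self.cuts


class TestConfigAndBounds:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            GAConfig(population_size=5)  # odd
        with pytest.raises(ValueError):
            GAConfig(crossover_rate=1.5)
        with pytest.raises(ValueError):
            GAConfig(elite_count=200)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            VariableBounds(("x",), (1.0,), (1.0,))


class TestInitPopulation:
    def test_shape_and_bounds(self):
        pop = init_population(DEFAULT_BOUNDS, 200, seed_or_rng=0)
        assert pop.shape == (200, 4)
        assert np.all(pop >= DEFAULT_BOUNDS.lo) and np.all(pop <= DEFAULT_BOUNDS.hi)

    def test_seeded_determinism(self):
        assert np.array_equal(init_population(BOX2, 50, 3),
                              init_population(BOX2, 50, 3))

    def test_uniform_law_mean(self):
        pop = init_population(BOX2, 10_000, 7)
        assert 4.8 <= pop[:, 0].mean() <= 5.2


class TestRoulette:
    def test_probabilities_proportional_after_shift(self):
        # fitness (0, 1): shifted weights ~ (eps, 1), P(second) ~ 1
        probs = _selection_probs(np.array([0.0, 1.0]))
        assert probs[1] >= 0.97

    def test_equal_fitness_uniform(self):
        probs = _selection_probs(np.array([5.0, 5.0, 5.0]))
        np.testing.assert_allclose(probs, 1 / 3)

    def test_empirical_frequencies(self, rng):
        pop = np.zeros((2, 1))
        fitness = np.array([0.0, 1.0])
        draws = np.array([roulette_select(pop, fitness, rng)
                          for _ in range(5000)]).ravel()
        assert (draws == 1).mean() >= 0.97

    def test_non_finite_fitness_rejected(self, rng):
        with pytest.raises(ValueError):
            roulette_select(np.zeros((2, 1)), np.array([np.inf, 1.0]), rng)


class TestCrossover:
    def test_prescribed_cuts_swap_middle_segment(self):
        c1, c2 = two_point_crossover([1, 2, 3, 4], [5, 6, 7, 8], rate=1.0,
                                     rng=FixedCutRng([1, 3]))
        np.testing.assert_array_equal(c1, [1, 6, 7, 4])
        np.testing.assert_array_equal(c2, [5, 2, 3, 8])

    def test_zero_rate_copies_parents(self, rng):
        p1, p2 = rng.normal(size=4), rng.normal(size=4)
        c1, c2 = two_point_crossover(p1, p2, rate=0.0, rng=rng)
        np.testing.assert_array_equal(c1, p1)
        np.testing.assert_array_equal(c2, p2)

    def test_gene_multiset_conserved(self, rng):
        for _ in range(50):
            p1, p2 = rng.normal(size=5), rng.normal(size=5)
            c1, c2 = two_point_crossover(p1, p2, rate=1.0, rng=rng)
            assert sorted(np.concatenate([c1, c2])) == pytest.approx(
                sorted(np.concatenate([p1, p2])))

    def test_short_chromosome_rejected(self, rng):
        with pytest.raises(ValueError):
            two_point_crossover([1.0], [2.0], 0.5, rng)


class TestMutation:
    def test_zero_rate_identity(self, rng):
        ind = np.array([1.0, 2.0, 14.0, 5.0])
        np.testing.assert_array_equal(
            uniform_mutation(ind, 0.0, DEFAULT_BOUNDS, rng), ind)

    def test_full_rate_redraws_within_bounds(self, rng):
        ind = np.array([0.0, 0.0, 13.0, 2.0])
        out = uniform_mutation(ind, 1.0, DEFAULT_BOUNDS, rng)
        assert np.all(out >= DEFAULT_BOUNDS.lo) and np.all(out <= DEFAULT_BOUNDS.hi)

    def test_expected_mutated_coordinate_count(self):
        rng = np.random.default_rng(5)
        ind = np.full(4, 5.0)
        bounds = VariableBounds(tuple("abcd"), (0.0,) * 4, (10.0,) * 4)
        total = 0
        n = 100_000
        for _ in range(n):
            out = uniform_mutation(ind, 0.03, bounds, rng)
            total += int((out != ind).sum())
        assert 0.11 <= total / n <= 0.13  # binomial mean 4 * 0.03


class TestGaMaximize:
    @staticmethod
    def quadratic(P):
        P = np.atleast_2d(P)
        return -((P[:, 0] - 3.0) ** 2) - ((P[:, 1] - 7.0) ** 2)

    def test_recovers_analytic_optimum(self):
        res = ga_maximize(self.quadratic, BOX2, GAConfig(seed=0))
        np.testing.assert_allclose(res.best_inputs, [3.0, 7.0], atol=0.05)

    def test_history_monotone_with_elitism(self):
        for seed in range(3):
            res = ga_maximize(self.quadratic, BOX2,
                              GAConfig(seed=seed, generations=100))
            assert np.all(np.diff(res.history) >= 0)

    def test_constant_objective_flat_history(self):
        res = ga_maximize(lambda P: np.zeros(np.atleast_2d(P).shape[0]),
                          BOX2, GAConfig(seed=1, generations=50))
        assert np.ptp(res.history) == 0.0
        assert np.all(res.best_inputs >= BOX2.lo)

    def test_population_respects_bounds_every_generation(self):
        seen = []

        def probe(P):
            P = np.atleast_2d(P)
            seen.append(P.copy())
            return self.quadratic(P)

        ga_maximize(probe, BOX2, GAConfig(seed=2, generations=50))
        all_pts = np.vstack(seen)
        assert np.all(all_pts >= BOX2.lo - 1e-12)
        assert np.all(all_pts <= BOX2.hi + 1e-12)

    def test_seeded_determinism(self):
        a = ga_maximize(self.quadratic, BOX2, GAConfig(seed=9, generations=50))
        b = ga_maximize(self.quadratic, BOX2, GAConfig(seed=9, generations=50))
        assert np.array_equal(a.best_inputs, b.best_inputs)
        assert np.array_equal(a.history, b.history)

    def test_matches_grid_scan_on_unimodal_1d(self):
        bounds = VariableBounds(("x",), (0.0,), (10.0,))

        def f(P):
            x = np.atleast_2d(P)[:, 0]
            return -np.abs(x - np.pi) ** 1.5

        res = ga_maximize(f, bounds, GAConfig(seed=4, generations=300))
        grid = np.linspace(0, 10, 10_001)
        best_grid = grid[np.argmax(f(grid[:, None]))]
        assert abs(res.best_inputs[0] - best_grid) <= 0.01

    def test_non_finite_objective_reported(self):
        def bad(P):
            P = np.atleast_2d(P)
            return np.where(P[:, 0] > 5, np.nan, 0.0)

        with pytest.raises(ValueError, match="non-finite"):
            ga_maximize(bad, BOX2, GAConfig(seed=0, generations=5))

    def test_scalar_objective_supported(self):
        res = ga_maximize(lambda x: -float((x[0] - 3) ** 2),
                          VariableBounds(("x", "y"), (0.0, 0.0), (10.0, 1.0)),
                          GAConfig(seed=0, generations=60,
                                   population_size=40))
        assert abs(res.best_inputs[0] - 3.0) < 0.1


class TestOptimizeModel:
    def test_near_point_box_collapses_to_that_point(self):
        bounds = VariableBounds(
            ("elicitor_conc", "mbcd_conc", "adding_day", "elapsed_days"),
            (2.999, 49.999, 16.999, 5.999), (3.001, 50.001, 17.001, 6.001))
        res = optimize_model(lambda Z: np.zeros(np.atleast_2d(Z).shape[0]),
                             bounds, GAConfig(seed=0, generations=5))
        np.testing.assert_allclose(res.best_inputs, [3.0, 50.0, 17.0, 6.0],
                                   atol=0.01)

    def test_harvest_cap_keeps_optimum_inside_data_region(self):
        # reward late harvests; the cap must stop the search at day 23
        def pred(Z):
            Z = np.atleast_2d(Z)
            return Z[:, 3]  # increasing in harvest day

        res = optimize_model(pred, DEFAULT_BOUNDS,
                             GAConfig(seed=1, generations=100),
                             max_harvest_day=23.0)
        assert res.extras["harvest_day"] <= 23.0 + 1e-9

    def test_seed_stability_of_best_value(self, trained_anfis):
        from elicitopt.anfis import predict
        vals = []
        for seed in (0, 1):
            res = optimize_model(
                lambda Z: predict(np.atleast_2d(Z), trained_anfis),
                DEFAULT_BOUNDS, GAConfig(seed=seed, generations=300),
                max_harvest_day=23.0)
            vals.append(res.best_predicted)
        assert abs(vals[0] - vals[1]) <= 0.02 * max(abs(v) for v in vals)
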
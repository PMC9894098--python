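import numpy as np
import pytest

from cellforge.ga import (
    GAConfig, GenerationLog, crossover, elitism, init_population, mutate,
    mutation_multipliers, run_ga, tournament_select,
)
from cellforge.ga.genome import SCALING_HIGH, SCALING_LOW
from cellforge.metrics import ObjectiveScores


def scores_arrays(pairs):
    s = [ObjectiveScores(a, b) for a, b in pairs]
    return (np.array([x.n_pass for x in s]), np.array([x.total for x in s]))


class TestInit:
    def test_uniform_mean(self):
        rng = np.random.default_rng(0)
        pop = init_population(2500, 4, rng)
        mean = (SCALING_LOW + SCALING_HIGH) / 2.0
        se = (SCALING_HIGH - SCALING_LOW) / np.sqrt(12.0) / np.sqrt(2500)
        for j in range(5):  # 4 channels + gap scale
            assert abs(pop[:, j].mean() - mean) < 3 * se

    def test_n_custom_uniform(self):
        from scipy.stats import chisquare
        rng = np.random.default_rng(1)
        pop = init_population(2500, 2, rng)
        counts = np.bincount(pop[:, 3].astype(int), minlength=6)[1:]
        assert counts.sum() == 2500
        assert chisquare(counts).pvalue > 1e-4

    def test_bounds(self):
        rng = np.random.default_rng(2)
        pop = init_population(1000, 3, rng)
        assert pop[:, :4].min() >= SCALING_LOW
        assert pop[:, :4].max() <= SCALING_HIGH
        assert set(np.unique(pop[:, 4])) <= {1.0, 2.0, 3.0, 4.0, 5.0}

    def test_determinism(self):
        a = init_population(100, 3, np.random.default_rng(7))
        b = init_population(100, 3, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)

    def test_empty_roster_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            init_population(10, 0, np.random.default_rng(0))

    def test_odd_population_rejected(self):
        with pytest.raises(ValueError):
            init_population(11, 2, np.random.default_rng(0))


class TestSelection:
    def test_pass_count_dominates(self):
        # A passes one objective, B none -> A wins every pairing
        pop = np.array([[1.0, 1.0, 1.0], [2.0, 2.0, 2.0]])
        n_pass, total = scores_arrays([(0.40, 0.60), (0.60, 0.60)])
        out = tournament_select(pop, n_pass, total, np.random.default_rng(0))
        np.testing.assert_array_equal(out, np.array([pop[0]] * 2))

    def test_total_breaks_ties(self):
        pop = np.array([[1.0, 1.0, 1.0], [2.0, 2.0, 2.0]])
        n_pass, total = scores_arrays([(0.60, 0.60), (0.55, 0.70)])
        out = tournament_select(pop, n_pass, total, np.random.default_rng(0))
        np.testing.assert_array_equal(out, np.array([pop[0]] * 2))

    def test_exact_tie_keeps_first_of_pair(self):
        pop = np.array([[1.0], [2.0]])
        n_pass, total = scores_arrays([(0.6, 0.6), (0.6, 0.6)])
        for seed in range(5):
            out = tournament_select(pop, n_pass, total, np.random.default_rng(seed))
            assert sorted(out.ravel()) in ([1.0, 1.0], [1.0, 2.0], [2.0, 2.0])

    def test_population_size_preserved_and_multiplicity(self):
        rng = np.random.default_rng(3)
        pop = np.arange(20.0).reshape(10, 2)
        n_pass = np.zeros(10)
        total = np.arange(10.0)
        out = tournament_select(pop, n_pass, total, rng)
        assert out.shape == pop.shape
        # each original advances 0, 1 or 2 times
        counts = [np.sum(np.all(out == row, axis=1)) for row in pop]
        assert all(c in (0, 1, 2) for c in counts)

    def test_odd_population_rejected(self):
        with pytest.raises(ValueError):
            tournament_select(np.zeros((3, 2)), np.zeros(3), np.zeros(3),
                              np.random.default_rng(0))


class TestCrossover:
    def test_zero_pair_prob_identity(self):
        pop = np.random.default_rng(0).uniform(size=(10, 4))
        out = crossover(pop, 0.0, 0.5, np.random.default_rng(1))
        np.testing.assert_array_equal(out, pop)

    def test_identical_parents_invariant(self):
        pop = np.ones((6, 3)) * 4.2
        out = crossover(pop, 0.9, 0.5, np.random.default_rng(2))
        np.testing.assert_array_equal(out, pop)

    def test_multiset_of_parameters_preserved(self):
        pop = np.random.default_rng(4).uniform(size=(8, 3))
        out = crossover(pop, 0.9, 0.5, np.random.default_rng(5))
        for j in range(3):
            np.testing.assert_allclose(np.sort(out[:, j]), np.sort(pop[:, j]))

    def test_swap_frequency(self):
        """Composed probability 0.9 x 0.5 = 0.45 within 3 SE over 1e5
        pair-parameter trials (all parent values distinct, so every swap is
        observable)."""
        rng = np.random.default_rng(6)
        n_pairs = 50_000
        pop = np.arange(float(2 * n_pairs * 2)).reshape(2 * n_pairs, 2)
        out = crossover(pop, 0.9, 0.5, rng)
        swapped = np.mean(out != pop)  # fraction of entries exchanged
        n_trials = n_pairs * 2
        se = np.sqrt(0.45 * 0.55 / n_trials)
        assert abs(swapped - 0.45) < 3 * se


class TestMutation:
    def test_zero_prob_identity(self):
        pop = np.random.default_rng(0).uniform(1, 2, size=(10, 4))
        out = mutate(pop, 0.0, 0.2, np.random.default_rng(1))
        np.testing.assert_array_equal(out, pop)

    def test_multipliers_within_half_to_double(self):
        m = mutation_multipliers(1_000_000, 0.2, np.random.default_rng(2))
        frac = np.mean((m >= 0.5) & (m <= 2.0))
        assert frac > 0.999

    def test_multiplier_median_near_one(self):
        m = mutation_multipliers(1_000_000, 0.2, np.random.default_rng(3))
        assert abs(np.median(m) - 1.0) < 5e-3

    def test_n_custom_integrality_and_bounds(self):
        rng = np.random.default_rng(4)
        pop = init_population(2000, 2, rng)
        out = mutate(pop, 0.5, 0.2, rng)
        ncol = out[:, 3]
        assert np.all(ncol == np.round(ncol))
        assert ncol.min() >= 1 and ncol.max() <= 5

    def test_values_may_exceed_initial_range(self):
        rng = np.random.default_rng(5)
        pop = np.full((2000, 2), 9.9)
        out = mutate(pop, 1.0, 0.2, rng)
        assert out[:, 0].max() > 10.0


class TestElitism:
    def test_worst_replaced_by_best_at_ten_percent(self):
        pop = np.arange(10.0)[:, None]
        n_pass = np.zeros(10)
        total = np.arange(10.0)  # row 0 best, row 9 worst
        out, np_o, tot_o = elitism(pop, n_pass, total, 0.10)
        assert out[9, 0] == 0.0
        assert tot_o[9] == 0.0
        np.testing.assert_array_equal(out[:9], pop[:9])

    def test_identical_population_unchanged(self):
        pop = np.ones((10, 2))
        out, _, _ = elitism(pop, np.zeros(10), np.ones(10), 0.10)
        np.testing.assert_array_equal(out, pop)

    def test_ranking_prefers_pass_count(self):
        pop = np.arange(10.0)[:, None]
        n_pass = np.array([2, 0, 0, 0, 0, 0, 0, 0, 0, 0])
        total = np.array([1.9, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9])
        out, _, _ = elitism(pop, n_pass, total, 0.10)
        assert out[9, 0] == 0.0  # the 2-pass genome is elite despite high total


def quadratic_evaluator(optimum):
    opt = np.asarray(optimum)

    def _eval(genome):
        d = np.abs(genome[:2] - opt)
        return ObjectiveScores(rmse_ap=float(d[0]), rmse_cat=float(d[1]))

    return _eval


class TestRunGa:
    def test_generations_zero_returns_scored_initial(self):
        cfg = GAConfig(population_size=20, generations=0, seed=5)
        log = run_ga(cfg, ("a", "b"), quadratic_evaluator([2.0, 3.0]))
        assert len(log.tables) == 1
        assert len(log.final) == 20

    def test_determinism(self):
        cfg = GAConfig(population_size=20, generations=2, seed=11)
        a = run_ga(cfg, ("a", "b"), quadratic_evaluator([2.0, 3.0]))
        b = run_ga(cfg, ("a", "b"), quadratic_evaluator([2.0, 3.0]))
        for ta, tb in zip(a.tables, b.tables):
            np.testing.assert_array_equal(ta.to_numpy(), tb.to_numpy())

    def test_acceptance_increases_on_surrogate(self):
        """Mean acceptance over seeds grows from generation 0 to the final
        generation on a closed-form objective."""
        first, last = [], []
        for seed in range(10):
            cfg = GAConfig(population_size=40, generations=3, seed=seed)
            log = run_ga(cfg, ("a", "b"), quadratic_evaluator([2.0, 3.0]))
            first.append(log.acceptance_fraction(0))
            last.append(log.acceptance_fraction(-1))
        assert np.mean(last) > np.mean(first)

    def test_best_total_non_increasing_with_elitism(self):
        cfg = GAConfig(population_size=40, generations=4, seed=3)
        log = run_ga(cfg, ("a", "b"), quadratic_evaluator([2.0, 3.0]))
        best = [t["rmse_ap"].add(t["rmse_cat"]).min() for t in log.tables]
        for g in range(1, len(best)):
            assert best[g] <= best[g - 1] + 1e-12

    def test_best_genome_approaches_optimum(self):
        cfg = GAConfig(population_size=60, generations=5, seed=9)
        log = run_ga(cfg, ("a", "b"), quadratic_evaluator([2.0, 3.0]))
        t0, tn = log.tables[0], log.tables[-1]
        def best_dist(t):
            tot = t["rmse_ap"] + t["rmse_cat"]
            return tot.min()
        assert best_dist(tn) < best_dist(t0)

    def test_empty_roster_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            run_ga(GAConfig(population_size=10, generations=1), (),
                   quadratic_evaluator([0.0, 0.0]))

    def test_failed_individuals_score_worst(self):
        from cellforge.coupling.simulate import SimulationError

        def flaky(genome):
            if genome[0] > 5.0:
                raise SimulationError("boom")
            return ObjectiveScores(rmse_ap=1.0, rmse_cat=1.0)

        cfg = GAConfig(population_size=20, generations=1, seed=2)
        log = run_ga(cfg, ("a",), flaky)
        failed = log.tables[0][log.tables[0]["scale_a"] > 5.0]
        assert len(failed) > 0
        assert np.all(np.isinf(failed["rmse_ap"]))


def test_log_save_round_trip(tmp_path):
    cfg = GAConfig(population_size=10, generations=1, seed=0)
    log = run_ga(cfg, ("a", "b"), quadratic_evaluator([1.0, 1.0]))
    log.save(tmp_path)
    assert (tmp_path / "generation_00.csv").exists()
    assert (tmp_path / "generation_01.csv").exists()
    assert (tmp_path / "manifest.json").exists()
    summary = log.accepted_summary()
    assert set(summary["parameter"]) == {"scale_a", "scale_b", "g_gap_scale", "n_custom"}
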
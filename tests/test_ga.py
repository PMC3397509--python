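"""Genetic-algorithm operators and the full selection loop."""

import numpy as np
import pytest

from qsar_garf.config import GAConfig
from qsar_garf.datasets import TRAIN
from qsar_garf.forest import fit_forest, oob_mse
from qsar_garf.ga import (FitnessEvaluator, double_point_crossover,
                          init_population, mutate, reinsert, run_ga,
                          select_parents)
from qsar_garf.synthetic import SyntheticSpec, generate_qsar


class FakeRng:
    """Deterministic stand-in driving crossover to chosen cut points."""

    def __init__(self, uniform_value, cuts):
        self._u = uniform_value
        self._cuts = np.array(cuts)

    def random(self, size=None):
        return self._u if size is None else np.full(size, self._u)

    def choice(self, a, size=2, replace=False):
        return self._cuts

    def integers(self, low, high=None, size=None):
        return 0


class TestInit:
    def test_single_locus_forced_to_one(self):
        pop = init_population(1, 8, np.random.default_rng(0))
        assert all(m.tolist() == [True] for m in pop)

    def test_reproducible(self):
        a = init_population(30, 10, np.random.default_rng(5))
        b = init_population(30, 10, np.random.default_rng(5))
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_mean_bits_binomial(self):
        p, size = 100, 50
        pop = init_population(p, size, np.random.default_rng(1))
        mean_bits = np.mean([m.sum() for m in pop])
        sigma = np.sqrt(p * 0.25 / size)
        assert abs(mean_bits - p / 2) < 5 * sigma


@pytest.fixture(scope="module")
def problem():
    spec = SyntheticSpec(n_compounds=100, n_descriptors=20,
                         n_informative=5, n_sparse_columns=0,
                         n_correlated_pairs=0, n_constant_columns=0,
                         seed=21)
    return generate_qsar(spec)


class TestFitness:

    def test_informative_mask_beats_noise_mask(self, problem):
        data, truth = problem
        names = data.matrix.descriptor_names
        inf = np.array([truth.roles[n] == "informative" for n in names])
        noise_idx = np.where(~inf)[0][:inf.sum()]
        noise = np.zeros(len(names), dtype=bool)
        noise[noise_idx] = True
        wins = 0
        for seed in range(10):
            cfg = GAConfig(rf_ntree=60, ga_seed=seed)
            ev = FitnessEvaluator(data.matrix.values, data.activity.pic50, cfg)
            wins += ev(inf) < ev(noise)
        assert wins >= 9

    def test_memoization_and_seed_derivation(self, problem):
        data, _ = problem
        cfg = GAConfig(rf_ntree=30, ga_seed=3)
        ev = FitnessEvaluator(data.matrix.values, data.activity.pic50, cfg)
        mask = np.zeros(20, dtype=bool)
        mask[:4] = True
        first, second = ev(mask), ev(mask)
        assert first == second and ev.cache_hits == 1

    def test_full_mask_equals_direct_forest(self, problem):
        data, _ = problem
        cfg = GAConfig(rf_ntree=40, ga_seed=1)
        ev = FitnessEvaluator(data.matrix.values, data.activity.pic50, cfg)
        full = np.ones(20, dtype=bool)
        direct = fit_forest(data.matrix.values, data.activity.pic50,
                            ntree=40, seed=ev.rf_seed(full))
        assert ev(full) == oob_mse(direct)

    def test_empty_mask_rejected(self, problem):
        data, _ = problem
        ev = FitnessEvaluator(data.matrix.values, data.activity.pic50,
                              GAConfig())
        with pytest.raises(ValueError):
            ev(np.zeros(20, dtype=bool))


class TestSelection:
    def test_two_individuals_best_selected_twice(self):
        pop = [np.array([True, False]), np.array([False, True])]
        # minimization: fitness 1.0 is the best of (1.0, 9.0)
        parents = select_parents(pop, [9.0, 1.0], 2, np.random.default_rng(0))
        assert all(np.array_equal(p, pop[1]) for p in parents)

    def test_equal_fitnesses_sample_uniformly(self):
        pop = [np.array([True]) for _ in range(10)]
        for i, m in enumerate(pop):
            pop[i] = np.array([True] * (i + 1))  # distinguishable lengths
        counts = np.zeros(10)
        parents = select_parents(pop, [2.0] * 10, 20, np.random.default_rng(3))
        for p in parents:
            counts[p.size - 1] += 1
        assert np.all(np.abs(counts - 2.0) <= 1.0)

    def test_reproducible_parent_list(self):
        pop = init_population(12, 6, np.random.default_rng(0))
        fits = list(range(6))
        a = select_parents(pop, fits, 5, np.random.default_rng(7))
        b = select_parents(pop, fits, 5, np.random.default_rng(7))
        assert all(np.array_equal(x, y) for x, y in zip(a, b))


class TestCrossover:
    def test_probability_zero_copies_parents(self):
        a = np.array([True] * 6)
        b = np.array([False, True] * 3)
        ca, cb = double_point_crossover(a, b, 0.0, np.random.default_rng(0))
        assert np.array_equal(ca, a) and np.array_equal(cb, b)

    def test_hand_worked_segment_swap(self):
        a = np.array([True] * 6)
        b = np.array([False] * 6)
        ca, cb = double_point_crossover(a, b, 1.0, FakeRng(0.0, [2, 4]))
        assert ca.tolist() == [True, True, False, False, True, True]
        assert cb.tolist() == [False, False, True, True, False, False]

    def test_bit_conservation_without_repair(self):
        g = np.random.default_rng(11)
        for _ in range(20):
            a, b = (g.random(12) < 0.5), (g.random(12) < 0.5)
            a[0] = b[0] = True            # preclude all-zero repair
            ca, cb = double_point_crossover(a, b, 1.0, g)
            if ca.any() and cb.any():
                assert ca.sum() + cb.sum() == a.sum() + b.sum()

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            double_point_crossover(np.ones(3, bool), np.ones(4, bool), 1.0,
                                   np.random.default_rng(0))


class TestMutation:
    def test_rate_zero_identity(self):
        m = np.array([True, False, True])
        assert np.array_equal(mutate(m, 0.0, np.random.default_rng(0)), m)

    def test_rate_one_complements(self):
        m = np.array([False, True, True, False])
        assert mutate(m, 1.0, np.random.default_rng(0)).tolist() == \
            [True, False, False, True]

    def test_expected_flip_count(self):
        p, trials, rate = 50, 400, 0.7 / 50
        g = np.random.default_rng(2)
        base = np.ones(p, dtype=bool)
        flips = [int((mutate(base, rate, g) != base).sum())
                 for _ in range(trials)]
        mean = np.mean(flips)
        sigma = np.sqrt(p * rate * (1 - rate) / trials)
        assert abs(mean - 0.7) < 5 * sigma


class TestReinsert:
    def test_strong_elite_survives(self):
        old = [np.array([True, False]), np.array([False, True])]
        new, fits = reinsert(old, [0.1, 5.0], [np.array([True, True])], [9.0])
        assert any(np.array_equal(m, old[0]) for m in new)
        assert min(fits) == 0.1

    def test_best_fitness_never_worsens(self):
        g = np.random.default_rng(4)
        old = init_population(6, 4, g)
        off = init_population(6, 3, g)
        old_f = [3.0, 1.0, 4.0, 2.0]
        _, fits = reinsert(old, old_f, off, [5.0, 6.0, 7.0])
        assert min(fits) <= min(old_f)

    def test_too_many_offspring_rejected(self):
        with pytest.raises(ValueError):
            reinsert([np.ones(2, bool)], [1.0],
                     [np.ones(2, bool)] * 2, [1.0, 2.0])


@pytest.fixture(scope="module")
def tiny():
    spec = SyntheticSpec(n_compounds=70, n_descriptors=15, n_informative=4,
                         n_sparse_columns=0, n_correlated_pairs=0,
                         n_constant_columns=0, seed=31)
    data, truth = generate_qsar(spec)
    return data.with_split([TRAIN] * 70), truth


class TestRunGA:

    def test_history_monotone_and_reproducible(self, tiny):
        data, _ = tiny
        cfg = GAConfig(population_size=10, max_generations=5, rf_ntree=25,
                       ga_seed=2)
        a = run_ga(data, cfg)
        best = [h[0] for h in a.history]
        assert best == sorted(best, reverse=True)
        b = run_ga(data, cfg)
        assert np.array_equal(a.best_mask, b.best_mask)
        assert a.best_fitness == b.best_fitness
        assert a.history == b.history

    def test_best_fitness_matches_reevaluation(self, tiny):
        data, _ = tiny
        cfg = GAConfig(population_size=8, max_generations=4, rf_ntree=25,
                       ga_seed=6)
        res = run_ga(data, cfg)
        ev = FitnessEvaluator(*data.training_xy(), cfg)
        assert ev(res.best_mask) == res.best_fitness
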
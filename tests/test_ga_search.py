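import numpy as np
import pytest

import sitefold as sf
from sitefold import ga_search
from sitefold.ga_search import (
    FeatureSubset,
    FitnessCache,
    ridge_logistic_newton,
    uniform_crossover,
)

from conftest import build_dataset


def _subset(bits, fitness, age=0):
    return FeatureSubset(mask=np.array(bits, bool), fitness=fitness, age=age)


class TestMutation:
    def test_zero_rate_is_identity(self):
        rng = np.random.default_rng(0)
        mask = np.array([1, 0, 1, 1, 0], bool)
        np.testing.assert_array_equal(sf.mutate_mask(mask, 0.0, rng), mask)

    def test_rate_one_is_complement(self):
        rng = np.random.default_rng(0)
        mask = np.array([1, 0, 1, 1, 0], bool)
        np.testing.assert_array_equal(
            sf.mutate_mask(mask, 1.0, rng), np.array([0, 1, 0, 0, 1], bool)
        )

    def test_all_zero_result_is_repaired_to_one_bit(self):
        rng = np.random.default_rng(0)
        out = sf.mutate_mask(np.array([True]), 1.0, rng)
        assert out.sum() == 1

    def test_expected_hamming_distance_matches_binomial_mean(self):
        rng = np.random.default_rng(12)
        mask = np.zeros(150, bool)
        mask[:20] = True
        dist = np.mean(
            [np.sum(sf.mutate_mask(mask, 0.02, rng) ^ mask) for _ in range(10_000)]
        )
        assert dist == pytest.approx(150 * 0.02, abs=0.2)


class TestTournament:
    def test_overwhelming_tournament_returns_best(self):
        pop = [_subset([1, 0, 0], 0.5), _subset([0, 1, 0], 0.9), _subset([0, 0, 1], 0.7)]
        rng = np.random.default_rng(0)
        # with-replacement draws of size 200 hit the best with near certainty
        assert sf.tournament_select(pop, 200, rng).fitness == 0.9

    def test_size_one_returns_a_population_member(self):
        pop = [_subset([1, 0], 0.5), _subset([0, 1], 0.6)]
        rng = np.random.default_rng(3)
        assert sf.tournament_select(pop, 1, rng) in pop

    def test_equal_fitness_prefers_smaller_subset(self):
        small = _subset([1, 1, 1, 0, 0, 0, 0], 0.8)
        big = _subset([1, 1, 1, 1, 1, 1, 1], 0.8)
        rng = np.random.default_rng(0)
        assert sf.tournament_select([small, big], 100, rng) is small


class TestFitness:
    def test_separating_feature_scores_one(self, two_site_signal_dataset):
        mask = np.zeros(5, bool)
        mask[0] = True
        fit = sf.evaluate_fitness(mask, two_site_signal_dataset, ["E", "F"])
        assert fit == pytest.approx(1.0)

    def test_noise_mask_stays_near_half(self, small_multisite):
        mask = np.ones(10, bool)
        fit = sf.evaluate_fitness(mask, small_multisite, ["P", "Q", "R"])
        assert 0.25 <= fit <= 0.75

    def test_fast_path_equals_generic_loso(self, small_multisite):
        rng = np.random.default_rng(5)
        mask = rng.random(10) < 0.5
        mask[0] = True
        spec = ga_search.default_ga_classifier()
        fast = sf.evaluate_fitness(mask, small_multisite, ["P", "Q", "R"], spec)
        generic = sf.leave_site_out_cv(
            small_multisite, spec, ["P", "Q", "R"], feature_mask=mask
        ).mean
        assert fast == pytest.approx(generic, abs=1e-9)

    def test_memoization_serves_second_call_from_cache(self, small_multisite):
        mask = np.ones(10, bool)
        cache = FitnessCache(small_multisite.fingerprint())
        v1 = sf.evaluate_fitness(mask, small_multisite, ["P", "Q", "R"], cache=cache)
        assert cache.misses == 1 and cache.hits == 0
        v2 = sf.evaluate_fitness(mask, small_multisite, ["P", "Q", "R"], cache=cache)
        assert v1 == v2
        assert cache.hits == 1 and cache.misses == 1

    def test_empty_mask_rejected(self, small_multisite):
        with pytest.raises(ValueError, match="empty"):
            sf.evaluate_fitness(np.zeros(10, bool), small_multisite, ["P", "Q"])


class TestNewtonSolver:
    def test_matches_sklearn_objective_minimizer(self):
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(0)
        for C in (0.1, 1.0, 10.0):
            Z = rng.normal(size=(150, 8))
            y = (rng.random(150) < 1 / (1 + np.exp(-Z[:, 0]))).astype(float)
            w, b = ridge_logistic_newton(Z, y, C=C)
            ref = LogisticRegression(C=C, solver="lbfgs", max_iter=5000, tol=1e-10).fit(Z, y)
            np.testing.assert_allclose(w, ref.coef_[0], atol=1e-6)
            assert b == pytest.approx(ref.intercept_[0], abs=1e-6)


class TestCrossover:
    def test_child_bits_come_from_parents(self):
        rng = np.random.default_rng(1)
        a = np.array([1, 1, 0, 0, 1], bool)
        b = np.array([0, 1, 1, 0, 0], bool)
        child = uniform_crossover(a, b, rng)
        both = a & b
        either = a | b
        assert np.all(child[both]) and not np.any(child[~either])


def _ga_dataset():
    """Small dataset with two strong signal features among 12."""
    ds = build_dataset(
        [("P", 15, 15), ("Q", 12, 14), ("R", 10, 10), ("CO", 12, 0), ("N1", 0, 18)],
        n_features=12,
        seed=6,
    )
    ds.X[:, 3] += 1.4 * ds.y
    ds.X[:, 7] += 1.4 * ds.y
    return ds


class TestRunVariant:
    FOLD_SITES = ["P", "Q", "R"]

    def test_generation_zero_is_the_evaluated_initial_population(self):
        ds = _ga_dataset()
        cfg = sf.GAConfig(population_size=12, n_generations=0, n_islands=2, k_top=30, seed=0)
        res = sf.run_ga_variant(ds, cfg, fold_sites=self.FOLD_SITES)
        assert res.n_requests == 12 * 2
        assert res.n_evaluations <= res.n_requests
        assert 0 < len(res.subsets) <= 30

    def test_same_seed_reproduces_result_exactly(self):
        ds = _ga_dataset()
        cfg = sf.GAConfig(population_size=10, n_generations=3, n_islands=2, k_top=20, seed=7)
        r1 = sf.run_ga_variant(ds, cfg, fold_sites=self.FOLD_SITES)
        r2 = sf.run_ga_variant(ds, cfg, fold_sites=self.FOLD_SITES)
        assert [s.fitness for s in r1.subsets] == [s.fitness for s in r2.subsets]
        for s1, s2 in zip(r1.subsets, r2.subsets):
            np.testing.assert_array_equal(s1.mask, s2.mask)

    def test_result_is_deduplicated_and_sorted(self):
        ds = _ga_dataset()
        cfg = sf.GAConfig(population_size=10, n_generations=4, n_islands=2, k_top=50, seed=1)
        res = sf.run_ga_variant(ds, cfg, fold_sites=self.FOLD_SITES)
        keys = [s.key for s in res.subsets]
        assert len(keys) == len(set(keys))
        ranks = [(-s.fitness, s.size, tuple(s.mask.astype(int))) for s in res.subsets]
        assert ranks == sorted(ranks)
        assert all(s.size >= 1 for s in res.subsets)

    def test_evaluation_budget_accounting(self):
        ds = _ga_dataset()
        P, G, I = 8, 5, 2
        cfg = sf.GAConfig(population_size=P, n_generations=G, n_islands=I, seed=2)
        res = sf.run_ga_variant(ds, cfg, fold_sites=self.FOLD_SITES)
        assert res.n_requests == P * (G + 1) * I
        assert res.n_evaluations <= res.n_requests

    def test_search_improves_on_random_initialization(self):
        ds = _ga_dataset()
        base = sf.GAConfig(population_size=14, n_generations=0, n_islands=1, seed=3)
        evolved = sf.GAConfig(population_size=14, n_generations=10, n_islands=1, seed=3)
        best0 = sf.run_ga_variant(ds, base, fold_sites=self.FOLD_SITES).subsets[0].fitness
        best1 = sf.run_ga_variant(ds, evolved, fold_sites=self.FOLD_SITES).subsets[0].fitness
        # archive keeps every evaluation, so more search can never rank lower
        assert best1 >= best0

    def test_no_signal_no_site_effects_fitness_stays_moderate(self):
        ds = build_dataset(
            [("P", 20, 20), ("Q", 18, 22), ("R", 15, 15)], n_features=12, seed=9
        )
        cfg = sf.GAConfig(population_size=16, n_generations=5, n_islands=1, seed=4)
        res = sf.run_ga_variant(ds, cfg, fold_sites=self.FOLD_SITES)
        assert res.subsets[0].fitness < 0.75

    def test_too_few_fold_sites_rejected(self):
        ds = _ga_dataset()
        cfg = sf.GAConfig(population_size=6, n_generations=1)
        with pytest.raises(ValueError, match="fold sites"):
            sf.run_ga_variant(ds, cfg, fold_sites=["P"])

    def test_signal_features_dominate_the_top_subsets(self):
        ds = _ga_dataset()
        cfg = sf.GAConfig(population_size=20, n_generations=12, n_islands=2, k_top=10, seed=5)
        res = sf.run_ga_variant(ds, cfg, fold_sites=self.FOLD_SITES)
        hits = sum(1 for s in res.subsets if s.mask[3] or s.mask[7])
        assert hits == len(res.subsets)


class TestPreset:
    def test_preset_has_six_distinct_variants(self):
        configs = sf.six_variant_preset(population_size=20, n_generations=10, seed=1)
        assert len(configs) == 6
        signatures = {
            (c.population_size, c.n_generations, c.init_prob) for c in configs
        }
        assert len(signatures) == 6
        assert all(c.k_top == 200 for c in configs)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            sf.GAConfig(population_size=1)
        with pytest.raises(ValueError):
            sf.GAConfig(mutation_rate=1.5)
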
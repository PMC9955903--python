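import numpy as np
import pytest

from genefs import (
    FitnessConfig,
    FitnessEvaluator,
    OptimizerConfig,
    SyntheticSpec,
    generate_dataset,
    optimize,
)
from genefs.fitness import exhaustive_best, exhaustive_search
from genefs.metaheuristics import (
    ALGORITHMS,
    GeneticAlgorithmSelector,
    binarize_position,
    make_selector,
    rda_offspring,
    reflect_bounds,
    sigmoid_transfer,
)

ALL_ALGOS = sorted(ALGORITHMS)


@pytest.fixture(scope="module")
def planted_pool():
    """10-gene pool with 2 planted genes at 2-SD effects, n = 60/60."""
    spec = SyntheticSpec(n_tumor=60, n_normal=60, n_genes=10, n_informative=2,
                         effect_sizes=(1.0, 1.0), base_sd_range=(0.5, 0.5),
                         seed=1000)
    return generate_dataset(spec)


@pytest.fixture(scope="module")
def shared_cache(planted_pool):
    return {}


class TestTransfer:
    def test_sigmoid_values(self):
        assert sigmoid_transfer(0.0) == pytest.approx(0.5)
        assert sigmoid_transfer(2.0) == pytest.approx(0.880797, abs=1e-6)
        v = np.linspace(-5, 5, 11)
        np.testing.assert_allclose(sigmoid_transfer(-v), 1 - sigmoid_transfer(v))

    def test_sigmoid_overflow_safe(self):
        assert sigmoid_transfer(-1e4) == 0.0
        assert sigmoid_transfer(1e4) == 1.0

    def test_binarize_saturation_and_repair(self):
        rng = np.random.default_rng(0)
        assert binarize_position(np.full(6, 50.0), rng).all()
        repaired = binarize_position(np.full(6, -50.0), rng)
        assert repaired.sum() == 1  # repair sets exactly one bit

    def test_binarize_reproducible_and_half_rate(self):
        a = binarize_position(np.zeros(3), np.random.default_rng(7))
        b = binarize_position(np.zeros(3), np.random.default_rng(7))
        assert (a == b).all()
        rng = np.random.default_rng(1)
        draws = np.mean([binarize_position(np.zeros(10), rng).mean()
                         for _ in range(2000)])
        assert draws == pytest.approx(0.5, abs=0.02)

    def test_reflection_keeps_box_and_interior_points(self):
        x = np.array([-7.0, 0.0, 6.0, 5.0])
        out = reflect_bounds(x, -5.0, 5.0)
        np.testing.assert_allclose(out, [-3.0, 0.0, 4.0, 5.0])


class TestFitness:
    def test_weight_one_is_cv_accuracy(self, planted_pool):
        ev = FitnessEvaluator(planted_pool.values, planted_pool.labels,
                              FitnessConfig(weight=1.0))
        mask = np.zeros(10, dtype=bool)
        mask[0] = True
        assert ev(mask) == pytest.approx(ev.cv_accuracy(mask))

    def test_parsimony_prefers_smaller_equal_accuracy(self, planted_pool):
        ev = FitnessEvaluator(planted_pool.values, planted_pool.labels,
                              FitnessConfig(weight=0.5))
        small = np.zeros(10, dtype=bool)
        small[2] = True
        big = np.ones(10, dtype=bool)
        acc_s, acc_b = ev.cv_accuracy(small), ev.cv_accuracy(big)
        f_s, f_b = ev(small), ev(big)
        assert f_s == pytest.approx(0.5 * acc_s + 0.5 * 0.9)
        assert f_b == pytest.approx(0.5 * acc_b + 0.5 * 0.0)

    def test_direct_recomputation_of_both_terms(self):
        # perfectly separable single feature
        rng = np.random.default_rng(4)
        y = np.array([0] * 30 + [1] * 30)
        X = np.column_stack([y * 10.0 + rng.normal(0, 0.1, 60),
                             rng.normal(size=60)])
        ev = FitnessEvaluator(X, y, FitnessConfig(weight=0.9))
        mask = np.array([True, False])
        assert ev.cv_accuracy(mask) == pytest.approx(1.0)
        assert ev(mask) == pytest.approx(0.9 * 1.0 + 0.1 * 0.5)

    def test_empty_mask_refused(self, planted_pool):
        ev = FitnessEvaluator(planted_pool.values, planted_pool.labels)
        with pytest.raises(ValueError, match="empty"):
            ev(np.zeros(10, dtype=bool))

    def test_degenerate_fold_refused(self):
        X = np.random.default_rng(0).normal(size=(8, 3))
        y = np.array([0, 0, 0, 0, 0, 0, 1, 1])
        with pytest.raises(ValueError, match="single-class"):
            FitnessEvaluator(X, y, FitnessConfig(cv=5))


class TestExhaustive:
    def test_surrogate_tiebreak_picks_bit_zero(self):
        best = exhaustive_search(lambda m: -float(m.sum()), 5)
        assert list(np.flatnonzero(best)) == [0]

    def test_four_candidate_bruteforce_table(self):
        # surrogate with a unique known argmax over all 15 masks
        weights = np.array([0.1, 0.9, 0.4, 0.3])

        def fitness(mask):
            return weights[mask].sum() - 0.25 * mask.sum()

        table = {}
        for code in range(1, 16):
            mask = np.array([(code >> j) & 1 for j in range(4)], dtype=bool)
            table[tuple(mask)] = fitness(mask)
        expected = max(table, key=table.get)
        got = exhaustive_search(fitness, 4)
        assert tuple(got) == expected

    def test_pool_size_guard(self, planted_pool):
        with pytest.raises(ValueError, match="max_pool"):
            exhaustive_best(planted_pool.values, planted_pool.labels, max_pool=5)


class TestOptimizers:
    @pytest.mark.parametrize("algorithm", ALL_ALGOS)
    def test_single_feature_pool_returns_it(self, algorithm):
        spec = SyntheticSpec(n_tumor=20, n_normal=20, n_genes=1, n_informative=1,
                             effect_sizes=(1.0,), seed=3)
        ds = generate_dataset(spec)
        mask, trace = optimize(ds, algorithm,
                               opt=OptimizerConfig(n_agents=5, max_iter=3, seed=0))
        assert mask.bits.tolist() == [True]
        assert len(trace.best_fitness) == 4

    @pytest.mark.parametrize("algorithm", ALL_ALGOS)
    def test_trace_monotone_and_final_fitness_rederived(self, planted_pool,
                                                        shared_cache, algorithm):
        selector = make_selector(algorithm,
                                 opt=OptimizerConfig(n_agents=8, max_iter=10, seed=5),
                                 cache=shared_cache)
        selector.fit(planted_pool.values, planted_pool.labels)
        trace = selector.trace_.best_fitness
        assert all(a <= b for a, b in zip(trace, trace[1:]))
        ev = FitnessEvaluator(planted_pool.values, planted_pool.labels,
                              FitnessConfig(), cache=dict(shared_cache))
        assert selector.best_fitness_ == pytest.approx(ev(selector.support_))
        assert selector.support_.any()

    @pytest.mark.parametrize("algorithm", ALL_ALGOS)
    def test_bit_identical_reruns(self, planted_pool, shared_cache, algorithm):
        results = []
        for _ in range(2):
            mask, trace = optimize(
                planted_pool, algorithm,
                opt=OptimizerConfig(n_agents=8, max_iter=8, seed=11),
                cache=shared_cache)
            results.append((mask.bits.tolist(), trace.best_fitness))
        assert results[0] == results[1]

    @pytest.mark.parametrize("algorithm", ALL_ALGOS)
    def test_max_iter_zero_returns_initial_best(self, planted_pool, shared_cache,
                                                algorithm):
        mask, trace = optimize(planted_pool, algorithm,
                               opt=OptimizerConfig(n_agents=6, max_iter=0, seed=2),
                               cache=shared_cache)
        assert len(trace.best_fitness) == 1
        assert mask.bits.any()

    def test_ga_without_operators_keeps_initial_best(self, planted_pool,
                                                     shared_cache):
        selector = GeneticAlgorithmSelector(n_agents=8, max_iter=6,
                                            crossover_rate=0.0, mutation_rate=0.0,
                                            random_state=9, cache=shared_cache)
        selector.fit(planted_pool.values, planted_pool.labels)
        trace = selector.trace_.best_fitness
        assert trace[-1] == pytest.approx(trace[0])

    def test_csa_full_abandonment_still_monotone(self, planted_pool, shared_cache):
        mask, trace = optimize(planted_pool, "csa",
                               opt=OptimizerConfig(n_agents=6, max_iter=10,
                                                   seed=3, pa=1.0),
                               cache=shared_cache)
        assert all(a <= b for a, b in zip(trace.best_fitness,
                                          trace.best_fitness[1:]))

    def test_rda_offspring_closed_form(self):
        parent = np.array([1.0, 0.0, 1.0, 0.0])
        off = rda_offspring(parent, parent, c=0.0)
        np.testing.assert_allclose(off, parent)
        assert ((off > 0.5) == parent.astype(bool)).all()

    @pytest.mark.parametrize("algorithm", ALL_ALGOS)
    def test_oracle_equivalence_smoke(self, planted_pool, shared_cache, algorithm):
        """Full-budget run recovers the exhaustive optimum on one instance."""
        oracle = exhaustive_best(planted_pool.values, planted_pool.labels,
                                 cache=shared_cache)
        mask, _ = optimize(planted_pool, algorithm,
                           opt=OptimizerConfig(seed=2000), cache=shared_cache)
        assert (mask.bits == oracle).all()
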
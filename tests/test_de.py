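"""Differential evolution operators and the run contract."""

import numpy as np
import pytest

from mirpanel import (
    CandidateVector,
    DEConfig,
    apply_elitism,
    crossover,
    init_population,
    mutate_scale,
    mutate_values,
    repair_duplicates,
    run_de,
    select,
)


def stub_fitness(indices):
    """Cheap deterministic pseudo-fitness used to exercise the optimizer."""
    return float((int(np.sum(indices)) * 2654435761 % 1000) / 1000.0)


class TestInitPopulation:
    def test_d_equals_n_pigeonhole(self, rng):
        cfg = DEConfig(n=5, pop_size=6, generations=1)
        pop = init_population(5, cfg, rng)
        for v in pop:
            assert sorted(v.indices.tolist()) == [1, 2, 3, 4, 5]

    def test_vectors_distinct_and_in_range(self, rng):
        cfg = DEConfig(n=8, pop_size=20, generations=1)
        pop = init_population(100, cfg, rng)
        assert len(pop) == 20
        for v in pop:
            v.validate(100)

    def test_deterministic_given_seed(self):
        cfg = DEConfig(n=4, pop_size=10, generations=1)
        a = init_population(50, cfg, np.random.default_rng(3))
        b = init_population(50, cfg, np.random.default_rng(3))
        for va, vb in zip(a, b):
            np.testing.assert_array_equal(va.indices, vb.indices)

    def test_too_few_features_rejected(self, rng):
        with pytest.raises(ValueError, match="distinct"):
            init_population(3, DEConfig(n=5, pop_size=4, generations=1), rng)


class TestMutateValues:
    def test_wraps_above_range(self):
        # 5 + floor(1 * (9 - 3)) = 11 -> subtract d -> 1
        out = mutate_values([5], [9], [3], F=1.0, d=10)
        assert out.tolist() == [1]

    def test_floor_arithmetic(self):
        # 2 + floor(0.5 * (7 - 4)) = 2 + 1 = 3
        out = mutate_values([2], [7], [4], F=0.5, d=10)
        assert out.tolist() == [3]

    def test_zero_factor_returns_base(self):
        vc, va, vb = [3, 7, 9], [1, 2, 3], [9, 8, 7]
        out = mutate_values(vc, va, vb, F=0.0, d=10)
        assert out.tolist() == vc

    def test_wraps_below_range(self):
        # 2 + floor(1 * (1 - 8)) = -5 -> add d -> 5
        out = mutate_values([2], [1], [8], F=1.0, d=10)
        assert out.tolist() == [5]

    def test_negative_floor_rounds_down(self):
        # floor(0.5 * (4 - 7)) = floor(-1.5) = -2
        out = mutate_values([5], [4], [7], F=0.5, d=10)
        assert out.tolist() == [3]

    def test_large_excursion_still_lands_in_range(self):
        out = mutate_values([10], [200], [1], F=2.0, d=10)
        assert 1 <= out[0] <= 10


class TestRepairDuplicates:
    def test_keeps_first_occurrence_replaces_rest(self, rng):
        out = repair_duplicates(np.array([4, 4, 4, 2]), d=6, rng=rng)
        assert out[0] == 4 and out[3] == 2
        assert len(set(out.tolist())) == 4
        assert set(out.tolist()) <= set(range(1, 7))

    def test_no_op_when_distinct(self, rng):
        v = np.array([5, 1, 3])
        np.testing.assert_array_equal(repair_duplicates(v, 6, rng), v)


class TestCrossover:
    def test_cr_one_keeps_trial(self, rng):
        trial = np.array([1, 2, 3, 4])
        target = np.array([5, 6, 7, 8])
        np.testing.assert_array_equal(crossover(trial, target, 1.0, 8, rng), trial)

    def test_cr_zero_restores_target(self, rng):
        trial = np.array([1, 2, 3, 4])
        target = np.array([5, 6, 7, 8])
        np.testing.assert_array_equal(crossover(trial, target, 0.0, 8, rng), target)

    def test_kept_fraction_matches_cr(self):
        rng = np.random.default_rng(12)
        trial = np.arange(1, 11)       # disjoint value sets: repair never
        target = np.arange(11, 21)     # interferes with provenance counting
        kept = 0
        total = 0
        for _ in range(1000):
            out = crossover(trial, target, 0.8, 20, rng)
            kept += int(np.isin(out, trial).sum())
            total += 10
        assert kept / total == pytest.approx(0.8, abs=0.02)


class TestSelectAndElitism:
    @pytest.mark.parametrize(
        "f_trial, f_target, winner",
        [(0.90, 0.80, "trial"), (0.80, 0.80, "target"), (0.70, 0.80, "target")],
    )
    def test_strict_improvement_rule(self, f_trial, f_target, winner):
        trial = CandidateVector([1, 2], f_trial)
        target = CandidateVector([3, 4], f_target)
        survivor = select(trial, target)
        assert survivor is (trial if winner == "trial" else target)

    def test_unset_fitness_rejected(self):
        with pytest.raises(ValueError, match="fitness"):
            select(CandidateVector([1, 2]), CandidateVector([3, 4], 0.5))

    def test_elitism_replaces_worst(self):
        prev_best = CandidateVector([1, 2], 0.95)
        pop = [CandidateVector([3, 4], 0.60), CandidateVector([5, 6], 0.70)]
        out = apply_elitism(prev_best, pop)
        fits = sorted(v.fitness for v in out)
        assert fits == [0.70, 0.95]

    def test_elitism_no_op_when_not_better(self):
        prev_best = CandidateVector([1, 2], 0.50)
        pop = [CandidateVector([3, 4], 0.60), CandidateVector([5, 6], 0.70)]
        out = apply_elitism(prev_best, pop)
        assert sorted(v.fitness for v in out) == [0.60, 0.70]

    def test_elitism_tie_favors_new_population(self):
        prev_best = CandidateVector([1, 2], 0.60)
        pop = [CandidateVector([3, 4], 0.60), CandidateVector([5, 6], 0.70)]
        out = apply_elitism(prev_best, pop)
        assert out[0].indices.tolist() == [3, 4]

    def test_elitism_copies_not_aliases(self):
        prev_best = CandidateVector([1, 2], 0.9)
        pop = [CandidateVector([3, 4], 0.1)]
        out = apply_elitism(prev_best, pop)
        assert out[0] is not prev_best
        np.testing.assert_array_equal(out[0].indices, prev_best.indices)


class TestMutateScale:
    def test_result_satisfies_invariants(self, rng):
        cfg = DEConfig(n=6, pop_size=10, generations=1)
        pop = init_population(30, cfg, rng)
        for j in range(10):
            trial = mutate_scale(pop, j, F=1.0, d=30, rng=rng)
            CandidateVector(trial).validate(30)

    def test_small_population_rejected(self, rng):
        pop = [CandidateVector([1, 2], 0.5)] * 3
        with pytest.raises(ValueError, match="at least 4"):
            mutate_scale(pop, 0, 1.0, 10, rng)


class TestRunDe:
    def test_history_non_decreasing_and_length(self):
        cfg = DEConfig(n=5, pop_size=8, generations=12)
        for seed in range(5):
            res = run_de(60, cfg, stub_fitness, np.random.default_rng(seed))
            assert len(res.history) == 13
            assert (np.diff(res.history) >= 0).all()

    def test_every_evaluated_vector_valid(self):
        seen = []

        def checking_fitness(indices):
            CandidateVector(indices).validate(40)
            seen.append(indices.copy())
            return stub_fitness(indices)

        cfg = DEConfig(n=6, pop_size=6, generations=8)
        run_de(40, cfg, checking_fitness, np.random.default_rng(1))
        assert len(seen) == 6 + 6 * 8

    def test_evaluation_accounting(self):
        cfg = DEConfig(n=4, pop_size=7, generations=9)
        res = run_de(30, cfg, stub_fitness, np.random.default_rng(2))
        assert res.n_initial_evaluations == 7
        assert res.n_trial_evaluations == 7 * 9

    def test_zero_generations_returns_initial_best(self):
        cfg = DEConfig(n=4, pop_size=6, generations=0)
        rng = np.random.default_rng(5)
        res = run_de(25, cfg, stub_fitness, rng)
        pop = init_population(25, cfg, np.random.default_rng(5))
        best = max(stub_fitness(v.indices) for v in pop)
        assert res.best.fitness == best
        assert res.history == [best]

    def test_deterministic_given_seed(self):
        cfg = DEConfig(n=5, pop_size=8, generations=6)
        a = run_de(50, cfg, stub_fitness, np.random.default_rng(9))
        b = run_de(50, cfg, stub_fitness, np.random.default_rng(9))
        np.testing.assert_array_equal(a.best.indices, b.best.indices)
        assert a.history == b.history
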
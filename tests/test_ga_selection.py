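"""GA wrapper feature selection: operator contracts, seeded
determinism, elitist monotonicity and planted-signal recovery."""

import numpy as np
import pandas as pd
import pytest

import qsarpipe as qp
from qsarpipe.ga_selection import (
    DescriptorSubset,
    GAConfig,
    crossover,
    mutate,
    run_ga,
    select_parents,
)


class TestEvaluateSubset:
    def test_zero_penalty_fitness_equals_raw(self, planted_classification):
        syn = planted_classification
        raw, fit = qp.evaluate_subset(
            syn.informative_columns, syn.matrix, syn.labels,
            "classification", penalty_per_descriptor=0.0, seed=0,
        )
        assert fit == raw

    def test_penalty_strictly_decreases_fitness_with_size(self, planted_classification):
        syn = planted_classification
        cols = list(syn.matrix.columns)
        small = qp.evaluate_subset(cols[:3], syn.matrix, syn.labels,
                                   "classification", penalty_per_descriptor=0.01, seed=0)
        raw_small, fit_small = small
        assert fit_small == pytest.approx(raw_small - 0.03)

    def test_seeded_determinism(self, planted_classification):
        syn = planted_classification
        a = qp.evaluate_subset(syn.informative_columns, syn.matrix, syn.labels,
                               "classification", seed=3)
        b = qp.evaluate_subset(syn.informative_columns, syn.matrix, syn.labels,
                               "classification", seed=3)
        assert a == b

    def test_unknown_column_is_error(self, planted_classification):
        syn = planted_classification
        with pytest.raises(ValueError, match="unknown descriptor"):
            qp.evaluate_subset(["nope"], syn.matrix, syn.labels, "classification")

    def test_planted_subset_beats_size_matched_noise(self):
        wins = 0
        n_trials = 20
        for seed in range(n_trials):
            syn = qp.make_synthetic_classification(
                n=250, d=40, n_informative=10, effect_size=2.0, seed=1000 + seed
            )
            noise_cols = [c for c in syn.matrix.columns
                          if c not in syn.informative_columns][:10]
            _, fit_planted = qp.evaluate_subset(
                syn.informative_columns, syn.matrix, syn.labels,
                "classification", seed=seed)
            _, fit_noise = qp.evaluate_subset(
                noise_cols, syn.matrix, syn.labels, "classification", seed=seed)
            wins += fit_planted > fit_noise
        assert wins > n_trials / 2


class TestSelectParents:
    def _pop(self, fits_sizes):
        return [
            DescriptorSubset(frozenset(f"d{i}_{j}" for j in range(size)),
                             raw_score=f, fitness=f)
            for i, (f, size) in enumerate(fits_sizes)
        ]

    def test_top_half_selected(self):
        pop = self._pop([(0.1 * i, 3) for i in range(10)])
        parents = select_parents(pop)
        assert len(parents) == 5
        assert min(p.fitness for p in parents) >= 0.5

    def test_ties_prefer_smaller_subsets(self):
        pop = self._pop([(0.5, s) for s in (5, 2, 8, 1, 3, 9, 4, 7, 6, 10)])
        parents = select_parents(pop)
        assert sorted(p.size for p in parents) == [1, 2, 3, 4, 5]

    def test_single_member_population(self):
        pop = self._pop([(0.9, 2)])
        assert select_parents(pop) == pop


class TestCrossover:
    def test_children_subset_of_parent_union(self, rng):
        a = DescriptorSubset(frozenset(f"a{i}" for i in range(6)), fitness=0)
        b = DescriptorSubset(frozenset(f"b{i}" for i in range(5)), fitness=0)
        for _ in range(50):
            c1, c2 = crossover(a, b, rng)
            assert c1 <= a.members | b.members
            assert c2 <= a.members | b.members

    def test_identical_parents_bound(self, rng):
        p = DescriptorSubset(frozenset(f"g{i}" for i in range(7)), fitness=0)
        c1, c2 = crossover(p, p, rng)
        assert c1 <= p.members and c2 <= p.members
        assert len(c1) <= len(p.members)

    def test_disjoint_parents_sizes(self, rng):
        a = DescriptorSubset(frozenset("abcd"), fitness=0)
        b = DescriptorSubset(frozenset("wxyz"), fitness=0)
        for _ in range(20):
            c1, c2 = crossover(a, b, rng)
            assert len(c1) == 4  # ceil(4/2) + floor(4/2)
            assert len(c2) == 4


class TestMutate:
    def test_zero_probs_identity(self, rng):
        members = frozenset("abc")
        assert mutate(members, list("abcdef"), rng, 0.0, 0.0) == members

    def test_size_floor_under_deletion(self, rng):
        for _ in range(30):
            out = mutate(frozenset("a"), list("abc"), rng, 0.0, 1.0)
            assert len(out) >= 1

    def test_mutation_skipped_when_pool_exhausted(self, rng):
        members = frozenset("abc")
        out = mutate(members, list("abc"), rng, 1.0, 0.0)
        assert out == members

    def test_mutation_fires_at_configured_rate(self):
        rng = np.random.default_rng(99)
        pool = [f"d{i}" for i in range(10)]
        members = frozenset(pool[:4])
        fired = 0
        trials = 10_000
        for _ in range(trials):
            out = mutate(members, pool, rng, 0.3, 0.0)
            fired += out != members
        assert fired / trials == pytest.approx(0.30, abs=0.015)


@pytest.fixture(scope="module")
def small_problem():
    return qp.make_synthetic_classification(
        n=200, d=20, n_informative=5, effect_size=2.0, seed=11
    )


class TestRunGA:
    def test_trace_monotone_and_pool_membership(self, small_problem):
        syn = small_problem
        res = run_ga(syn.matrix, syn.labels, "classification",
                     GAConfig(population_size=10, generations=6, seed=2))
        diffs = res.trace["best_fitness"].diff().dropna()
        assert (diffs >= -1e-12).all()
        pool = set(syn.matrix.columns)
        for s in res.population:
            assert s.members <= pool

    def test_seed_determinism(self, small_problem):
        syn = small_problem
        cfg = GAConfig(population_size=8, generations=4, seed=5)
        r1 = run_ga(syn.matrix, syn.labels, "classification", cfg)
        r2 = run_ga(syn.matrix, syn.labels, "classification", cfg)
        pd.testing.assert_frame_equal(r1.trace, r2.trace)
        assert [s.members for s in r1.population] == [s.members for s in r2.population]

    def test_single_generation_contract(self, small_problem):
        syn = small_problem
        res = run_ga(syn.matrix, syn.labels, "classification",
                     GAConfig(population_size=8, generations=1, seed=1))
        assert len(res.trace) == 1
        assert len(res.population) <= 8

    def test_empty_pool_is_error(self):
        with pytest.raises(ValueError, match="empty candidate pool"):
            run_ga(pd.DataFrame(), [0, 1], "classification", GAConfig())

    def test_recovers_planted_descriptors(self):
        """One seeded recovery run; the full 10-run study lives in the
        acceptance suite."""
        syn = qp.make_synthetic_classification(
            n=300, d=60, n_informative=8, effect_size=2.0, seed=100
        )
        res = run_ga(syn.matrix, syn.labels, "classification",
                     GAConfig(population_size=24, generations=30, seed=0))
        recovered = len(res.best.members & set(syn.informative_columns))
        assert recovered >= 6

    def test_regression_task_runs(self):
        syn = qp.make_synthetic_regression(
            n=150, d=15, n_informative=4, coef_scale=1.0, noise_sd=0.5, seed=3
        )
        res = run_ga(syn.matrix, syn.labels, "regression",
                     GAConfig(population_size=8, generations=3, seed=0))
        assert res.best.raw_score > 0.5
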
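"""Genetic-algorithm wrapper feature selection.

Descriptor subsets are chromosomes. Each subset is scored by the mean
five-fold cross-validated performance (F1 for classification, R^2 for
regression) of a model trained on just those columns, minus a linear
size penalty so that smaller subsets win ties on raw performance. Each
generation keeps the top half of the population as parents (elitism),
pairs them, produces two children per pair by recombining half of each
parent's descriptors, and perturbs children by mutation (swap one
descriptor, 30% probability) and deletion (drop one descriptor, 30%
probability).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.metrics import f1_score
from sklearn.model_selection import KFold, StratifiedKFold

Task = Literal["classification", "regression"]


@dataclass(frozen=True)
class DescriptorSubset:
    """A GA chromosome: a set of descriptor names with its scores."""

    members: frozenset[str]
    raw_score: float = float("nan")
    fitness: float = float("nan")
    generation_born: int = 0

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("subset must be non-empty")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class GAConfig:
    population_size: int = 50
    generations: int = 200
    parent_fraction: float = 0.5
    mutation_prob: float = 0.3
    deletion_prob: float = 0.3
    cv_folds: int = 5
    penalty_per_descriptor: float = 0.001
    initial_inclusion_prob: float = 0.5
    # alternative reading of "randomly selecting 50% of the available
    # descriptors": restrict the whole initial population to one random
    # half of the pool
    restrict_initial_pool: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("parent_fraction", "mutation_prob", "deletion_prob",
                     "initial_inclusion_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")


def default_estimator(task: Task, seed: int = 0):
    """Light-weight scoring model used inside the wrapper CV.

    Wrapper selection evaluates thousands of candidate subsets, so the
    inner model must be cheap; a regularized linear model ranks subsets
    reliably and any heavier estimator can be supplied instead.
    """
    if task == "classification":
        return LogisticRegression(max_iter=200, random_state=seed)
    return Ridge(alpha=1.0, random_state=seed)


def evaluate_subset(
    subset: DescriptorSubset | Sequence[str],
    matrix: pd.DataFrame,
    labels: Sequence,
    task: Task,
    cv_folds: int = 5,
    penalty_per_descriptor: float = 0.001,
    seed: int = 0,
    estimator_factory: Callable | None = None,
) -> tuple[float, float]:
    """Return ``(raw_score, fitness)`` for a descriptor subset.

    raw_score is the mean fold score (F1 or R^2) of the estimator
    trained on the subset's columns; fitness subtracts the linear size
    penalty. Folds are drawn with ``seed`` (stratified for
    classification), so repeated evaluation is deterministic.
    """
    members = sorted(subset.members if isinstance(subset, DescriptorSubset) else subset)
    unknown = [m for m in members if m not in matrix.columns]
    if unknown:
        raise ValueError(f"unknown descriptor column(s): {unknown[:5]}")
    X = matrix[members].to_numpy(dtype=float)
    y = np.asarray(labels)

    factory = estimator_factory or (lambda: default_estimator(task, seed))
    if task == "classification":
        splitter = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)

    scores = []
    for train_idx, test_idx in splitter.split(X, y):
        model = factory()
        model.fit(X[train_idx], y[train_idx])
        pred = model.predict(X[test_idx])
        if task == "classification":
            scores.append(f1_score(y[test_idx], pred, zero_division=0))
        else:
            yt = y[test_idx].astype(float)
            ss_tot = np.sum((yt - yt.mean()) ** 2)
            score = 1.0 - np.sum((yt - pred) ** 2) / ss_tot if ss_tot > 0 else 0.0
            scores.append(score)
    raw = float(np.mean(scores))
    fitness = raw - penalty_per_descriptor * len(members)
    return raw, fitness


def select_parents(
    population: Sequence[DescriptorSubset], parent_fraction: float = 0.5
) -> list[DescriptorSubset]:
    """Top ``ceil(parent_fraction * N)`` subsets by fitness; ties broken
    by smaller subset size, then stable input order."""
    n_parents = max(1, int(np.ceil(parent_fraction * len(population))))
    indexed = list(enumerate(population))
    indexed.sort(key=lambda t: (-t[1].fitness, t[1].size, t[0]))
    return [s for _, s in indexed[:n_parents]]


def crossover(
    parent_a: DescriptorSubset,
    parent_b: DescriptorSubset,
    rng: np.random.Generator,
) -> tuple[frozenset[str], frozenset[str]]:
    """Two children, each the union of a random half of each parent.

    Child 1 takes ceil(|A|/2) of A plus floor(|B|/2) of B; child 2 takes
    the complementary halves. Shared descriptors collapse by set union.
    """
    a = sorted(parent_a.members)
    b = sorted(parent_b.members)
    a_perm = [a[i] for i in rng.permutation(len(a))]
    b_perm = [b[i] for i in rng.permutation(len(b))]
    a_cut = int(np.ceil(len(a) / 2))
    b_cut = int(np.floor(len(b) / 2))
    child1 = frozenset(a_perm[:a_cut]) | frozenset(b_perm[:b_cut])
    child2 = frozenset(a_perm[a_cut:]) | frozenset(b_perm[b_cut:])
    # a degenerate split can leave a child empty (e.g. |A|=1, |B|=1);
    # fall back to inheriting the smaller parent whole
    if not child1:
        child1 = frozenset(a)
    if not child2:
        child2 = frozenset(b)
    return child1, child2


def mutate(
    members: frozenset[str],
    pool: Sequence[str],
    rng: np.random.Generator,
    mutation_prob: float = 0.3,
    deletion_prob: float = 0.3,
) -> frozenset[str]:
    """Swap one member for a random non-member with ``mutation_prob``;
    independently drop one member with ``deletion_prob``. Size never
    falls below 1; mutation is skipped when no non-members exist."""
    current = set(members)
    if rng.random() < mutation_prob:
        outside = sorted(set(pool) - current)
        if outside:
            victim = sorted(current)[rng.integers(len(current))]
            newcomer = outside[rng.integers(len(outside))]
            current.discard(victim)
            current.add(newcomer)
    if rng.random() < deletion_prob and len(current) > 1:
        victim = sorted(current)[rng.integers(len(current))]
        current.discard(victim)
    return frozenset(current)


@dataclass
class GAResult:
    population: list[DescriptorSubset]  # sorted by fitness, best first
    trace: pd.DataFrame  # generation, best_fitness, best_raw, best_size

    @property
    def best(self) -> DescriptorSubset:
        return self.population[0]


def run_ga(
    matrix: pd.DataFrame,
    labels: Sequence,
    task: Task,
    config: GAConfig | None = None,
    estimator_factory: Callable | None = None,
) -> GAResult:
    """Evolve descriptor subsets for ``config.generations`` generations.

    Parents survive into the next generation (elitism), so the
    best-fitness trace is non-decreasing. Scored subsets are cached by
    membership, which keeps re-scored survivors cheap.
    """
    config = config or GAConfig()
    pool = list(matrix.columns)
    if not pool:
        raise ValueError("empty candidate pool")
    rng = np.random.default_rng(config.seed)

    if config.restrict_initial_pool:
        half = max(1, len(pool) // 2)
        idx = rng.choice(len(pool), size=half, replace=False)
        init_pool = [pool[i] for i in sorted(idx)]
    else:
        init_pool = pool

    cache: dict[frozenset[str], tuple[float, float]] = {}

    def score(members: frozenset[str], born: int) -> DescriptorSubset:
        if members not in cache:
            cache[members] = evaluate_subset(
                members,
                matrix,
                labels,
                task,
                cv_folds=config.cv_folds,
                penalty_per_descriptor=config.penalty_per_descriptor,
                seed=config.seed,
                estimator_factory=estimator_factory,
            )
        raw, fit = cache[members]
        return DescriptorSubset(members, raw_score=raw, fitness=fit, generation_born=born)

    population: list[DescriptorSubset] = []
    while len(population) < config.population_size:
        mask = rng.random(len(init_pool)) < config.initial_inclusion_prob
        members = frozenset(c for c, m in zip(init_pool, mask) if m)
        if not members:
            members = frozenset([init_pool[rng.integers(len(init_pool))]])
        population.append(score(members, 0))

    trace_rows = []
    for gen in range(1, config.generations + 1):
        parents = select_parents(population, config.parent_fraction)
        children: list[DescriptorSubset] = []
        order = rng.permutation(len(parents))
        for i in range(0, len(order) - 1, 2):
            pa, pb = parents[order[i]], parents[order[i + 1]]
            for child_members in crossover(pa, pb, rng):
                child_members = mutate(
                    child_members,
                    pool,
                    rng,
                    config.mutation_prob,
                    config.deletion_prob,
                )
                children.append(score(child_members, gen))
        merged = parents + children
        merged.sort(key=lambda s: (-s.fitness, s.size))
        population = merged[: config.population_size]
        best = population[0]
        trace_rows.append(
            {
                "generation": gen,
                "best_fitness": best.fitness,
                "best_raw": best.raw_score,
                "best_size": best.size,
            }
        )

    population.sort(key=lambda s: (-s.fitness, s.size))
    return GAResult(population=population, trace=pd.DataFrame(trace_rows))


def write_ga_outputs(result: GAResult, trace_path, subsets_path) -> None:
    """Trace as CSV; final subsets as a JSON list of name arrays."""
    import json

    result.trace.to_csv(trace_path, index=False)
    with open(subsets_path, "w") as fh:
        json.dump([sorted(s.members) for s in result.population], fh, indent=1)
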
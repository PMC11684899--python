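"""Multi-objective optimizers: a reference NSGA-style GA for wrapper
feature selection and the dual-stage overestimation-adjusted wrapper.

The GA evolves binary feature masks with uniform crossover, a
specialized mutation whose expected effect is removing and adding
``mutation_strength`` features regardless of panel size, clone handling
(offspring identical to an existing mask are re-mutated, then dropped),
and NSGA-II survivor selection (non-dominated sorting with a
crowding-distance tie-break).  Every evaluated solution enters a hall
of fame; the returned solution set is the non-dominated front of all
solutions ever explored.

The dual-stage wrapper runs in three steps: (1) the tuning optimizer is
run inside a k-fold CV loop and each fold's front is re-scored on the
fold's left-out samples, yielding observed overestimations; (2) one
regression adjuster per objective is trained on those samples, weighted
by the hypervolume partial derivatives; (3) the main optimizer is run
on all training data with the adjusted objectives, so the reported
fitness of the final front is already corrected for the winner's curse.

Both optimizers are also exposed as scikit-learn style estimators
(``GAFeatureSelector``, ``DosaMOSelector``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Union

import numpy as np
from sklearn.base import BaseEstimator

from .adjusters import build_adjuster_samples, fit_adjuster
from .core import (
    Dataset,
    EvaluatedSolution,
    FeatureSet,
    ObjectiveSpec,
    SolutionSet,
    create_folds,
    nondominated_front,
)
from .objectives import make_adjusted_objective

logger = logging.getLogger("dosamo")

__all__ = [
    "OptimizerConfig",
    "DosaConfig",
    "ga_optimize",
    "dosa_optimize",
    "evaluate_on_holdout",
    "GAFeatureSelector",
    "DosaMOSelector",
    "OPTIMIZER_REGISTRY",
    "get_optimizer",
]

_SEED_MOD = 2**31


@dataclass
class OptimizerConfig:
    """Budget and variation settings of the reference GA."""

    population_size: int = 20
    generations: int = 10
    crossover_rate: float = 0.9
    mutation_strength: float = 1.0  # expected features removed and added
    init_max_features: int = 10
    clone_retry_budget: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 4 or self.population_size % 2:
            raise ValueError("population_size must be even and >= 4")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if not 0.0 <= self.crossover_rate <= 1.0:
            raise ValueError("crossover_rate must lie in [0, 1]")

    def halved(self) -> "OptimizerConfig":
        """Reduced-budget variant used for the step-1 tuning runs."""
        return replace(
            self,
            population_size=max(4, (self.population_size // 2 + 1) // 2 * 2),
            generations=max(1, self.generations // 2),
        )


@dataclass
class DosaConfig:
    """Dual-stage wrapper settings.

    ``adjuster_kinds`` is one adjuster name for every objective or a
    per-objective list.
    """

    k_outer: int = 3
    main: OptimizerConfig = field(default_factory=OptimizerConfig)
    tuning: Optional[OptimizerConfig] = None
    adjuster_kinds: Union[str, Sequence[str]] = "dummy"

    def __post_init__(self) -> None:
        if self.k_outer < 2:
            raise ValueError("k_outer must be >= 2")
        if self.tuning is None:
            self.tuning = self.main.halved()

    def kinds_for(self, m: int) -> List[str]:
        if isinstance(self.adjuster_kinds, str):
            return [self.adjuster_kinds] * m
        kinds = list(self.adjuster_kinds)
        if len(kinds) != m:
            raise ValueError("need one adjuster kind per objective")
        return kinds


# ---------------------------------------------------------------------------
# NSGA-II style survivor selection
# ---------------------------------------------------------------------------

def _nondominated_sort(F: np.ndarray) -> List[np.ndarray]:
    """Successive non-dominated fronts (without duplicate collapsing)."""
    remaining = np.arange(F.shape[0])
    fronts = []
    while remaining.size:
        sub = F[remaining]
        flags = np.zeros(len(remaining), dtype=bool)
        for i in range(len(remaining)):
            better = np.all(sub >= sub[i], axis=1) & np.any(sub > sub[i], axis=1)
            flags[i] = not np.any(better)
        fronts.append(remaining[flags])
        remaining = remaining[~flags]
    return fronts


def _crowding_distance(F: np.ndarray) -> np.ndarray:
    n, m = F.shape
    d = np.zeros(n)
    if n <= 2:
        return np.full(n, np.inf)
    for j in range(m):
        order = np.argsort(F[:, j], kind="stable")
        span = F[order[-1], j] - F[order[0], j]
        d[order[0]] = d[order[-1]] = np.inf
        if span <= 0:
            continue
        d[order[1:-1]] += (F[order[2:], j] - F[order[:-2], j]) / span
    return d


def _select_survivors(F: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    chosen: List[int] = []
    for front in _nondominated_sort(F):
        if len(chosen) + len(front) <= k:
            chosen.extend(front.tolist())
            continue
        d = _crowding_distance(F[front])
        # stable, deterministic: sort by (-distance, index)
        order = np.lexsort((front, -d))
        chosen.extend(front[order][: k - len(chosen)].tolist())
        break
    return np.array(chosen, dtype=int)


# ---------------------------------------------------------------------------
# reference GA
# ---------------------------------------------------------------------------

def _mutate(mask: np.ndarray, alpha: float, rng: np.random.Generator) -> np.ndarray:
    out = mask.copy()
    p = mask.shape[0]
    s = int(mask.sum())
    u = rng.random(p)
    if s > 0:
        out[mask & (u < alpha / max(1, s))] = False
    if p - s > 0:
        out[~mask & (u < alpha / (p - s))] = True
    return out


def ga_optimize(
    config: OptimizerConfig,
    objectives: Sequence[ObjectiveSpec],
    data: Dataset,
) -> SolutionSet:
    """Run the reference GA and return the front of all explored solutions."""
    if not objectives:
        raise ValueError("at least one objective is required")
    if data.n_samples == 0:
        raise ValueError("training data is empty")
    p = data.n_features
    rng = np.random.default_rng(config.seed)
    eval_seed = config.seed % _SEED_MOD
    hof: dict = {}

    def evaluate(mask: np.ndarray) -> EvaluatedSolution:
        key = mask.tobytes()
        if key in hof:
            return hof[key]
        fs = FeatureSet.from_mask(mask)
        fits, sds = [], []
        for obj in objectives:
            try:
                ev = obj.evaluate(fs, data, eval_seed)
            except Exception:
                logger.error("objective %r failed during evaluation", obj.name)
                raise
            fits.append(ev.fitness)
            sds.append(ev.sd)
        sol = EvaluatedSolution(fs, np.array(fits), np.array(sds))
        hof[key] = sol
        return sol

    def random_mask() -> np.ndarray:
        s = int(rng.integers(1, min(config.init_max_features, p) + 1))
        mask = np.zeros(p, dtype=bool)
        mask[rng.choice(p, size=s, replace=False)] = True
        return mask

    # initialization (unique masks)
    population: List[np.ndarray] = []
    seen = set()
    while len(population) < config.population_size:
        mask = random_mask()
        if mask.tobytes() in seen:
            continue
        seen.add(mask.tobytes())
        population.append(mask)
    for mask in population:
        evaluate(mask)

    for gen in range(config.generations):
        order = rng.permutation(config.population_size)
        offspring: List[np.ndarray] = []
        current = {m.tobytes() for m in population}
        for a, b in zip(order[::2], order[1::2]):
            pa, pb = population[a], population[b]
            if rng.random() < config.crossover_rate:
                swap = rng.random(p) < 0.5
                ca = np.where(swap, pb, pa)
                cb = np.where(swap, pa, pb)
            else:
                ca, cb = pa.copy(), pb.copy()
            for child in (ca, cb):
                child = _mutate(child, config.mutation_strength, rng)
                if not child.any():
                    child[rng.integers(0, p)] = True
                retries = 0
                while child.tobytes() in current and retries < config.clone_retry_budget:
                    child = _mutate(child, config.mutation_strength, rng)
                    if not child.any():
                        child[rng.integers(0, p)] = True
                    retries += 1
                if child.tobytes() in current:
                    continue  # persistent clone: drop
                current.add(child.tobytes())
                offspring.append(child)
        for mask in offspring:
            evaluate(mask)
        combined = population + offspring
        F = np.vstack([hof[m.tobytes()].original_fitness for m in combined])
        keep = _select_survivors(F, config.population_size, rng)
        population = [combined[i] for i in keep]
        logger.debug("generation %d: %d evaluations so far", gen + 1, len(hof))

    result = SolutionSet(
        solutions=list(hof.values()),
        objectives=list(objectives),
        stats={"n_evaluations": len(hof)},
    ).finalized()
    logger.info(
        "GA finished: %d evaluations, front size %d", len(hof), len(result)
    )
    return result


# ---------------------------------------------------------------------------
# dual-stage wrapper
# ---------------------------------------------------------------------------

def evaluate_on_holdout(
    solution_set: SolutionSet,
    train_data: Dataset,
    holdout_data: Dataset,
    objectives: Sequence[ObjectiveSpec],
) -> np.ndarray:
    """Holdout fitness matrix X' : refit each panel on ``train_data`` in
    full and measure every objective on ``holdout_data``."""
    n, m = len(solution_set), len(objectives)
    X_test = np.zeros((n, m))
    for i, sol in enumerate(solution_set.solutions):
        for j, obj in enumerate(objectives):
            v = obj.evaluate_holdout(sol.feature_set, train_data, holdout_data)
            X_test[i, j] = min(1.0, max(0.0, float(v)))
    return X_test


def dosa_optimize(
    config: DosaConfig,
    objectives: Sequence[ObjectiveSpec],
    data: Dataset,
) -> SolutionSet:
    """Run the full dual-stage procedure; see the module docstring."""
    m = len(objectives)
    kinds = config.kinds_for(m)
    seed = config.main.seed % _SEED_MOD

    # step 1: per-fold fronts and their left-out performance
    folds = create_folds(data, config.k_outer, seed)
    fold_hofs: List[SolutionSet] = []
    for i, (train_idx, test_idx) in enumerate(folds):
        fold_train = data.subset(train_idx)
        fold_test = data.subset(test_idx)
        cfg_i = replace(config.tuning, seed=(seed + 1 + i) % _SEED_MOD)
        hof = ga_optimize(cfg_i, objectives, fold_train)
        if len(hof) == 0:
            logger.warning("fold %d produced an empty front; skipped", i)
            continue
        T = evaluate_on_holdout(hof, fold_train, fold_test, objectives)
        for s_i, sol in enumerate(hof.solutions):
            sol.test_fitness = T[s_i]
        fold_hofs.append(hof)
        logger.info("fold %d: front of %d solutions scored on left-out part", i, len(hof))
    if not fold_hofs and any(k != "zero" for k in kinds):
        raise RuntimeError("every fold produced an empty front; cannot train adjusters")

    # step 2: one adjuster per objective
    adjusted = []
    adjusters = []
    all_samples = []
    for j, obj in enumerate(objectives):
        samples = build_adjuster_samples(fold_hofs, folds, j)
        adjuster = fit_adjuster(kinds[j], samples, seed=(seed + 101 + j) % _SEED_MOD)
        adjusters.append(adjuster)
        all_samples.extend(samples)
        adjusted.append(make_adjusted_objective(obj, adjuster))
        logger.info(
            "objective %r: %s adjuster trained on %d samples",
            obj.name,
            kinds[j],
            len(samples),
        )

    # step 3: main run on all training data with adjusted objectives
    logger.info("final optimization with adjusted objectives")
    result = ga_optimize(config.main, adjusted, data)
    tuning_evals = sum(h.stats.get("n_evaluations", 0) for h in fold_hofs)
    result.stats["n_evaluations_tuning"] = tuning_evals
    result.stats["adjusters"] = adjusters
    result.stats["fold_hofs"] = fold_hofs
    result.stats["adjuster_samples"] = all_samples
    result.objectives = list(objectives)  # report under the base objective specs
    return result


OPTIMIZER_REGISTRY = {"nsga2": ga_optimize}


def get_optimizer(name: str):
    try:
        return OPTIMIZER_REGISTRY[name]
    except KeyError:
        raise ValueError(
            f"unknown optimizer {name!r}; known: {sorted(OPTIMIZER_REGISTRY)}"
        ) from None


# ---------------------------------------------------------------------------
# scikit-learn estimator facades
# ---------------------------------------------------------------------------

def _build_dataset(X, y, time, event, feature_names) -> Dataset:
    return Dataset(X=np.asarray(X, dtype=float), y=y, time=time, event=event,
                   feature_names=feature_names)


class GAFeatureSelector(BaseEstimator):
    """Multi-objective GA wrapper feature selection, estimator-style.

    Parameters mirror :class:`OptimizerConfig`; ``objectives`` is a list
    of :class:`~dosamo.core.ObjectiveSpec`.  After ``fit`` the Pareto
    front of all evaluated panels is available as ``solution_set_``.
    """

    def __init__(
        self,
        objectives=None,
        population_size: int = 20,
        generations: int = 10,
        crossover_rate: float = 0.9,
        mutation_strength: float = 1.0,
        init_max_features: int = 10,
        clone_retry_budget: int = 3,
        random_state: int = 0,
    ):
        self.objectives = objectives
        self.population_size = population_size
        self.generations = generations
        self.crossover_rate = crossover_rate
        self.mutation_strength = mutation_strength
        self.init_max_features = init_max_features
        self.clone_retry_budget = clone_retry_budget
        self.random_state = random_state

    def _config(self) -> OptimizerConfig:
        return OptimizerConfig(
            population_size=self.population_size,
            generations=self.generations,
            crossover_rate=self.crossover_rate,
            mutation_strength=self.mutation_strength,
            init_max_features=self.init_max_features,
            clone_retry_budget=self.clone_retry_budget,
            seed=self.random_state,
        )

    def fit(self, X, y=None, *, time=None, event=None, feature_names=None):
        if not self.objectives:
            raise ValueError("objectives must be a non-empty list")
        data = _build_dataset(X, y, time, event, feature_names)
        self.n_features_in_ = data.n_features
        self.solution_set_ = ga_optimize(self._config(), self.objectives, data)
        return self

    def get_support(self, solution: int = 0) -> np.ndarray:
        """Boolean mask of the features selected by one front solution."""
        return self.solution_set_.solutions[solution].feature_set.mask

    def transform(self, X, solution: int = 0) -> np.ndarray:
        return np.asarray(X)[:, self.get_support(solution)]


class DosaMOSelector(BaseEstimator):
    """Dual-stage overestimation-adjusted feature selection.

    Wraps the GA with the three-step adjustment procedure; after
    ``fit`` the final front is in ``solution_set_``, with the trained
    adjusters in ``adjusters_`` and the step-1 regression samples in
    ``adjuster_samples_``.
    """

    def __init__(
        self,
        objectives=None,
        adjuster_kind="dummy",
        k_outer: int = 3,
        population_size: int = 20,
        generations: int = 10,
        crossover_rate: float = 0.9,
        mutation_strength: float = 1.0,
        init_max_features: int = 10,
        clone_retry_budget: int = 3,
        tuning_population_size: Optional[int] = None,
        tuning_generations: Optional[int] = None,
        random_state: int = 0,
    ):
        self.objectives = objectives
        self.adjuster_kind = adjuster_kind
        self.k_outer = k_outer
        self.population_size = population_size
        self.generations = generations
        self.crossover_rate = crossover_rate
        self.mutation_strength = mutation_strength
        self.init_max_features = init_max_features
        self.clone_retry_budget = clone_retry_budget
        self.tuning_population_size = tuning_population_size
        self.tuning_generations = tuning_generations
        self.random_state = random_state

    def _config(self) -> DosaConfig:
        main = OptimizerConfig(
            population_size=self.population_size,
            generations=self.generations,
            crossover_rate=self.crossover_rate,
            mutation_strength=self.mutation_strength,
            init_max_features=self.init_max_features,
            clone_retry_budget=self.clone_retry_budget,
            seed=self.random_state,
        )
        tuning = main.halved()
        if self.tuning_population_size is not None:
            tuning = replace(tuning, population_size=self.tuning_population_size)
        if self.tuning_generations is not None:
            tuning = replace(tuning, generations=self.tuning_generations)
        return DosaConfig(
            k_outer=self.k_outer,
            main=main,
            tuning=tuning,
            adjuster_kinds=self.adjuster_kind,
        )

    def fit(self, X, y=None, *, time=None, event=None, feature_names=None):
        if not self.objectives:
            raise ValueError("objectives must be a non-empty list")
        data = _build_dataset(X, y, time, event, feature_names)
        self.n_features_in_ = data.n_features
        result = dosa_optimize(self._config(), self.objectives, data)
        self.solution_set_ = result
        self.adjusters_ = result.stats.get("adjusters", [])
        self.fold_hofs_ = result.stats.get("fold_hofs", [])
        self.adjuster_samples_ = result.stats.get("adjuster_samples", [])
        return self

    def get_support(self, solution: int = 0) -> np.ndarray:
        return self.solution_set_.solutions[solution].feature_set.mask

    def transform(self, X, solution: int = 0) -> np.ndarray:
        return np.asarray(X)[:, self.get_support(solution)]
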
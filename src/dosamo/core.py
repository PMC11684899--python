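"""Shared domain types, Pareto utilities, and fold partitioning.

The objects here are deliberately small: a dataset container for
expression-like matrices with classification and/or survival outcomes,
a feature subset (candidate biomarker panel), evaluated solutions and
solution sets, and the fold bookkeeping used by the dual-stage
optimizer.  All fitness values are maximized scores in ``[0, 1]``.
"""

from __future__ import annotations

import logging
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

logger = logging.getLogger("dosamo")

__all__ = [
    "Dataset",
    "FeatureSet",
    "ObjectiveSpec",
    "FitnessEvaluation",
    "EvaluatedSolution",
    "SolutionSet",
    "FoldsData",
    "dominates",
    "nondominated_front",
    "create_folds",
]


@dataclass
class Dataset:
    """Samples-by-features numeric matrix plus per-sample outcomes.

    Parameters
    ----------
    X : ndarray of shape (n_samples, n_features)
        Expression-like numeric matrix.
    y : ndarray of shape (n_samples,), optional
        Class labels for classification objectives.
    time, event : ndarray of shape (n_samples,), optional
        Right-censored survival outcome; ``event`` is 1 for an observed
        event and 0 for censoring.
    feature_names : sequence of str, optional
        Defaults to ``f0 .. f{p-1}``.
    sample_ids : sequence of str, optional
    """

    X: np.ndarray
    y: Optional[np.ndarray] = None
    time: Optional[np.ndarray] = None
    event: Optional[np.ndarray] = None
    feature_names: Optional[Sequence[str]] = None
    sample_ids: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D samples x features matrix")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains non-finite entries")
        n = self.X.shape[0]
        for name in ("y", "time", "event"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v)
                if v.shape != (n,):
                    raise ValueError(f"{name} must have length n_samples={n}")
                setattr(self, name, v)
        if (self.time is None) != (self.event is None):
            raise ValueError("survival outcome needs both time and event")
        if self.feature_names is None:
            self.feature_names = [f"f{j}" for j in range(self.X.shape[1])]
        elif len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length mismatch")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def has_classes(self) -> bool:
        return self.y is not None

    @property
    def has_survival(self) -> bool:
        return self.time is not None

    def subset(self, idx: np.ndarray) -> "Dataset":
        """Row-subset the dataset (samples), keeping all features."""
        idx = np.asarray(idx)
        return Dataset(
            X=self.X[idx],
            y=None if self.y is None else self.y[idx],
            time=None if self.time is None else self.time[idx],
            event=None if self.event is None else self.event[idx],
            feature_names=self.feature_names,
            sample_ids=None
            if self.sample_ids is None
            else [self.sample_ids[i] for i in np.atleast_1d(idx)],
        )


@dataclass(frozen=True)
class FeatureSet:
    """An individual/solution: the selected feature indices of a panel."""

    indices: tuple
    n_total: int

    def __post_init__(self) -> None:
        idx = tuple(sorted(set(int(i) for i in self.indices)))
        object.__setattr__(self, "indices", idx)
        if any(i < 0 or i >= self.n_total for i in idx):
            raise ValueError("feature index out of range")

    @property
    def size(self) -> int:
        return len(self.indices)

    @property
    def mask(self) -> np.ndarray:
        m = np.zeros(self.n_total, dtype=bool)
        if self.indices:
            m[list(self.indices)] = True
        return m

    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "FeatureSet":
        return cls(tuple(np.flatnonzero(mask)), int(mask.shape[0]))


@dataclass
class FitnessEvaluation:
    """One objective evaluation: fitness in [0,1], its SD, and panel size."""

    fitness: float
    sd: float
    n_features: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.fitness <= 1.0):
            raise ValueError(f"fitness {self.fitness} outside [0, 1]")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


class ObjectiveSpec(ABC):
    """A maximized fitness function mapping (feature set, dataset) -> [0,1].

    ``kind`` is ``"model_metric"`` for objectives that train an inner
    model under cross-validation, ``"parsimony"`` for deterministic
    panel-size scores (whose SD is 0 by construction).
    """

    name: str = "objective"
    kind: str = "model_metric"

    @abstractmethod
    def evaluate(
        self, feature_set: FeatureSet, data: Dataset, seed: int
    ) -> FitnessEvaluation:
        """Training-data fitness estimate (inner CV for model metrics)."""

    @abstractmethod
    def evaluate_holdout(
        self, feature_set: FeatureSet, train: Dataset, holdout: Dataset
    ) -> float:
        """Fitness of the model refit on ``train``, measured on ``holdout``."""


@dataclass
class EvaluatedSolution:
    feature_set: FeatureSet
    original_fitness: np.ndarray
    fitness_sd: np.ndarray
    test_fitness: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.original_fitness = np.asarray(self.original_fitness, dtype=float)
        self.fitness_sd = np.asarray(self.fitness_sd, dtype=float)
        if self.test_fitness is not None:
            self.test_fitness = np.asarray(self.test_fitness, dtype=float)
        if self.original_fitness.shape != self.fitness_sd.shape:
            raise ValueError("fitness and sd vectors must share length")
        if np.any(self.fitness_sd < 0):
            raise ValueError("fitness_sd entries must be >= 0")


@dataclass
class SolutionSet:
    """A hall-of-fame front: evaluated solutions plus their objectives."""

    solutions: list
    objectives: list = field(default_factory=list)
    stats: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.solutions)

    def fitness_matrix(self) -> np.ndarray:
        if not self.solutions:
            m = len(self.objectives)
            return np.zeros((0, m))
        return np.vstack([s.original_fitness for s in self.solutions])

    def sd_matrix(self) -> np.ndarray:
        if not self.solutions:
            return np.zeros((0, len(self.objectives)))
        return np.vstack([s.fitness_sd for s in self.solutions])

    def test_fitness_matrix(self) -> np.ndarray:
        if not self.solutions:
            return np.zeros((0, len(self.objectives)))
        rows = []
        for s in self.solutions:
            if s.test_fitness is None:
                raise ValueError("solution lacks test fitness")
            rows.append(s.test_fitness)
        return np.vstack(rows)

    def finalized(self) -> "SolutionSet":
        """Keep one representative per unique feature set, then the
        non-dominated front of the remaining fitness rows."""
        seen = {}
        for s in self.solutions:
            key = s.feature_set.indices
            if key not in seen:
                seen[key] = s
        sols = list(seen.values())
        if not sols:
            return SolutionSet([], self.objectives, dict(self.stats))
        F = np.vstack([s.original_fitness for s in sols])
        keep = nondominated_front(F)
        return SolutionSet(
            [sols[i] for i in sorted(keep)], self.objectives, dict(self.stats)
        )


@dataclass
class FoldsData:
    """A k-fold partition of a dataset's samples."""

    dataset: Dataset
    k: int
    assignment: np.ndarray  # per-sample fold index in {0..k-1}

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        if self.assignment.shape != (self.dataset.n_samples,):
            raise ValueError("assignment must cover every sample")
        if set(np.unique(self.assignment)) - set(range(self.k)):
            raise ValueError("fold index outside {0..k-1}")

    def split(self, fold: int) -> tuple:
        """(train_idx, test_idx) for one fold."""
        test = np.flatnonzero(self.assignment == fold)
        train = np.flatnonzero(self.assignment != fold)
        return train, test

    def __iter__(self) -> Iterator[tuple]:
        for f in range(self.k):
            yield self.split(f)


def dominates(a: np.ndarray, b: np.ndarray) -> bool:
    """Maximization Pareto dominance: ``a`` >= ``b`` everywhere, > somewhere."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    return bool(np.all(a >= b) and np.any(a > b))


def nondominated_front(points: np.ndarray) -> set:
    """Indices of rows dominated by no other row.

    Duplicate rows on the front are collapsed to their lowest index so
    the returned representatives have unique fitness vectors.
    """
    P = np.asarray(points, dtype=float)
    if P.size == 0:
        return set()
    if not np.all(np.isfinite(P)):
        raise ValueError("fitness matrix must be finite")
    n = P.shape[0]
    keep = set()
    # pairwise dominance, vectorized per row; n is at most a few hundred
    for i in range(n):
        diff_ge = np.all(P >= P[i], axis=1)
        diff_gt = np.any(P > P[i], axis=1)
        if np.any(diff_ge & diff_gt):
            continue  # someone dominates row i
        dup = np.flatnonzero(np.all(P == P[i], axis=1))
        if dup[0] == i:
            keep.add(i)
    return keep


def create_folds(dataset: Dataset, k: int, seed: int) -> FoldsData:
    """Deterministic k-fold partition, stratified when possible.

    Classification data is stratified by class label, survival data by
    the event indicator.  If some stratum has fewer than ``k`` members
    the split falls back to a plain shuffled partition with a warning.
    """
    n = dataset.n_samples
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds n_samples={n}")
    strata = None
    if dataset.has_classes:
        strata = dataset.y
    elif dataset.has_survival:
        strata = dataset.event
    assignment = np.empty(n, dtype=int)
    if strata is not None:
        _, counts = np.unique(strata, return_counts=True)
        if counts.min() < k:
            logger.warning(
                "smallest stratum has %d < k=%d members; "
                "falling back to non-stratified folds",
                counts.min(),
                k,
            )
            strata = None
    if strata is not None:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(n), strata)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(n))
    for f, (_, test_idx) in enumerate(splits):
        assignment[test_idx] = f
    logger.info("created %d folds over %d samples", k, n)
    return FoldsData(dataset=dataset, k=k, assignment=assignment)
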
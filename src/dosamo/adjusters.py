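"""Overestimation regressors and their training-sample construction.

Step 1 of the dual-stage optimizer produces, for every fold and every
solution on that fold's front, a training row with three meta-features
(original inner-CV fitness, its SD, panel size) and the observed
overestimation (original minus left-out fitness) as target.  Rows are
weighted by the partial derivative of the hypervolume at that solution
and objective, scaled to sum to 1 within each fold.

Six regressor kinds are provided.  ``zero`` predicts no overestimation
(the unadjusted optimizer); ``dummy`` is the weighted median — the
constant minimizer of the weighted absolute error; ``ptree`` a pruned
absolute-error decision tree; ``rfreg`` a random forest; ``svr`` an
RBF epsilon-SVR on standardized inputs; ``rsvr`` the same SVR with its
regularization chosen by random search.  Absolute error is minimized
wherever the underlying model allows it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

from .core import FoldsData, SolutionSet
from .hypervolume import assign_weights

__all__ = [
    "AdjusterSample",
    "weighted_median",
    "ZeroAdjuster",
    "DummyAdjuster",
    "PrunedTreeAdjuster",
    "ForestAdjuster",
    "SVRAdjuster",
    "TunedSVRAdjuster",
    "ADJUSTER_KINDS",
    "make_adjuster",
    "fit_adjuster",
    "predict_overestimation",
    "build_adjuster_samples",
    "train_adjuster",
    "samples_to_frame",
    "samples_from_frame",
]

META_FEATURES = ("original_fitness", "fitness_sd", "n_features")


@dataclass
class AdjusterSample:
    """One regression row: meta-features -> overestimation, with weight."""

    original_fitness: float
    fitness_sd: float
    n_features: int
    overestimation: float
    weight: float
    fold: int = 0
    objective: int = 0

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("weight must be >= 0")
        if self.fitness_sd < 0:
            raise ValueError("fitness_sd must be >= 0")


def weighted_median(values: Sequence[float], weights: Sequence[float]) -> float:
    """Minimizer of ``sum_i w_i |v_i - c|``; lowest value among minimizers."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise ValueError("weighted_median of empty values")
    if np.any(w < 0):
        raise ValueError("weights must be >= 0")
    total = w.sum()
    if total == 0:
        w = np.ones_like(w)
        total = w.sum()
    order = np.argsort(v, kind="stable")
    cum = np.cumsum(w[order])
    i = int(np.searchsorted(cum, total / 2.0))
    return float(v[order][i])


def _as_xyw(X, y=None, sample_weight=None):
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("adjuster inputs must be (n, 3) meta-feature rows")
    if y is not None:
        y = np.asarray(y, dtype=float)
        if len(y) != len(X):
            raise ValueError("X and y length mismatch")
    if sample_weight is None:
        sample_weight = np.ones(len(X))
    sample_weight = np.asarray(sample_weight, dtype=float)
    return X, y, sample_weight


class BaseAdjuster:
    """fit((n,3) meta-features, overestimation, weights) / predict((q,3))."""

    kind = "base"
    is_fitted = False

    def fit(self, X, y, sample_weight=None):
        raise NotImplementedError

    def predict(self, X) -> np.ndarray:
        raise NotImplementedError

    def _check_fitted(self) -> None:
        if not self.is_fitted:
            raise ValueError(f"{self.kind} adjuster is not fitted")


class ZeroAdjuster(BaseAdjuster):
    """No adjustment: predicts zero overestimation everywhere."""

    kind = "zero"
    is_fitted = True  # constant model, nothing to learn

    def fit(self, X, y, sample_weight=None):
        return self

    def predict(self, X) -> np.ndarray:
        X, _, _ = _as_xyw(X)
        return np.zeros(len(X))


class DummyAdjuster(BaseAdjuster):
    """Constant predictor: the weighted median of the overestimations."""

    kind = "dummy"

    def fit(self, X, y, sample_weight=None):
        X, y, w = _as_xyw(X, y, sample_weight)
        self.constant_ = weighted_median(y, w)
        self.is_fitted = True
        return self

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        X, _, _ = _as_xyw(X)
        return np.full(len(X), self.constant_)


def _weighted_mae(y_true, y_pred, w) -> float:
    w = np.asarray(w, dtype=float)
    tot = w.sum()
    if tot == 0:
        return float(np.mean(np.abs(y_true - y_pred)))
    return float(np.sum(w * np.abs(y_true - y_pred)) / tot)


class PrunedTreeAdjuster(BaseAdjuster):
    """Absolute-error regression tree, cost-complexity pruned by CV.

    Candidate pruning strengths come from the tree's own cost-complexity
    path; the one minimizing the weighted MAE under (up to) 5-fold CV is
    kept.
    """

    kind = "ptree"

    def __init__(self, seed: int = 0, max_depth: int = 8, cv: int = 5):
        self.seed = seed
        self.max_depth = max_depth
        self.cv = cv

    def _tree(self, ccp_alpha: float = 0.0) -> DecisionTreeRegressor:
        return DecisionTreeRegressor(
            criterion="absolute_error",
            max_depth=self.max_depth,
            ccp_alpha=ccp_alpha,
            random_state=self.seed,
        )

    def fit(self, X, y, sample_weight=None):
        X, y, w = _as_xyw(X, y, sample_weight)
        path = self._tree().cost_complexity_pruning_path(X, y, sample_weight=w)
        alphas = np.unique(np.clip(path.ccp_alphas, 0.0, None))
        best_alpha = 0.0
        n_splits = min(self.cv, len(X))
        if len(alphas) > 1 and n_splits >= 2:
            kf = KFold(n_splits=n_splits, shuffle=True, random_state=self.seed)
            scores = np.zeros(len(alphas))
            for train_idx, test_idx in kf.split(X):
                for a_i, alpha in enumerate(alphas):
                    t = self._tree(alpha).fit(
                        X[train_idx], y[train_idx], sample_weight=w[train_idx]
                    )
                    scores[a_i] += _weighted_mae(
                        y[test_idx], t.predict(X[test_idx]), w[test_idx]
                    )
            best_alpha = float(alphas[int(np.argmin(scores))])
        self.tree_ = self._tree(best_alpha).fit(X, y, sample_weight=w)
        self.ccp_alpha_ = best_alpha
        self.is_fitted = True
        return self

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        X, _, _ = _as_xyw(X)
        return self.tree_.predict(X)


class ForestAdjuster(BaseAdjuster):
    """Random-forest regressor on the meta-features (absolute error)."""

    kind = "rfreg"

    def __init__(self, seed: int = 0, n_estimators: int = 500):
        self.seed = seed
        self.n_estimators = n_estimators

    def fit(self, X, y, sample_weight=None):
        X, y, w = _as_xyw(X, y, sample_weight)
        self.forest_ = RandomForestRegressor(
            n_estimators=self.n_estimators,
            criterion="absolute_error",
            min_samples_leaf=5,
            random_state=self.seed,
            n_jobs=1,
        )
        self.forest_.fit(X, y, sample_weight=w)
        self.is_fitted = True
        return self

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        X, _, _ = _as_xyw(X)
        return self.forest_.predict(X)


class SVRAdjuster(BaseAdjuster):
    """Epsilon-SVR (RBF) on standardized meta-features, fixed C and eps."""

    kind = "svr"

    def __init__(self, C: float = 1.0, epsilon: float = 0.01):
        self.C = C
        self.epsilon = epsilon

    def _pipeline(self) -> Pipeline:
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("svr", SVR(kernel="rbf", C=self.C, epsilon=self.epsilon)),
            ]
        )

    def fit(self, X, y, sample_weight=None):
        X, y, w = _as_xyw(X, y, sample_weight)
        self.model_ = self._pipeline()
        self.model_.fit(X, y, svr__sample_weight=w)
        self.is_fitted = True
        return self

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        X, _, _ = _as_xyw(X)
        return self.model_.predict(X)


class TunedSVRAdjuster(BaseAdjuster):
    """SVR with C and epsilon tuned by random search on weighted MAE.

    30 draws, log-uniform C in [1e-2, 1e3] and epsilon in [1e-3, 1e-1],
    scored by (up to) 5-fold CV.
    """

    kind = "rsvr"

    def __init__(self, seed: int = 0, n_iter: int = 30, cv: int = 5):
        self.seed = seed
        self.n_iter = n_iter
        self.cv = cv

    def fit(self, X, y, sample_weight=None):
        X, y, w = _as_xyw(X, y, sample_weight)
        rng = np.random.default_rng(self.seed)
        Cs = 10.0 ** rng.uniform(-2, 3, size=self.n_iter)
        epss = 10.0 ** rng.uniform(-3, -1, size=self.n_iter)
        n_splits = min(self.cv, len(X))
        best = (1.0, 0.01)
        if n_splits >= 2:
            kf = KFold(n_splits=n_splits, shuffle=True, random_state=self.seed)
            splits = list(kf.split(X))
            best_score = np.inf
            for C, eps in zip(Cs, epss):
                score = 0.0
                for train_idx, test_idx in splits:
                    m = SVRAdjuster(C=C, epsilon=eps)
                    m.fit(X[train_idx], y[train_idx], w[train_idx])
                    score += _weighted_mae(
                        y[test_idx], m.predict(X[test_idx]), w[test_idx]
                    )
                if score < best_score:
                    best_score, best = score, (float(C), float(eps))
        self.C_, self.epsilon_ = best
        inner = SVRAdjuster(C=self.C_, epsilon=self.epsilon_)
        inner.fit(X, y, w)
        self.model_ = inner
        self.is_fitted = True
        return self

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        return self.model_.predict(X)


ADJUSTER_KINDS = ("zero", "dummy", "ptree", "rfreg", "svr", "rsvr")


def make_adjuster(kind: str, seed: int = 0) -> BaseAdjuster:
    if kind == "zero":
        return ZeroAdjuster()
    if kind == "dummy":
        return DummyAdjuster()
    if kind == "ptree":
        return PrunedTreeAdjuster(seed=seed)
    if kind == "rfreg":
        return ForestAdjuster(seed=seed)
    if kind == "svr":
        return SVRAdjuster()
    if kind == "rsvr":
        return TunedSVRAdjuster(seed=seed)
    raise ValueError(f"unknown adjuster kind {kind!r}; expected one of {ADJUSTER_KINDS}")


def fit_adjuster(
    kind: str, samples: Iterable[AdjusterSample], seed: int = 0
) -> BaseAdjuster:
    """Fit one adjuster of the given kind on training samples."""
    samples = list(samples)
    model = make_adjuster(kind, seed=seed)
    if kind == "zero":
        return model
    if not samples:
        raise ValueError(f"adjuster kind {kind!r} needs at least one sample")
    X = np.array(
        [[s.original_fitness, s.fitness_sd, s.n_features] for s in samples]
    )
    y = np.array([s.overestimation for s in samples])
    w = np.array([s.weight for s in samples])
    return model.fit(X, y, sample_weight=w)


def predict_overestimation(
    model: BaseAdjuster, original_fitness: float, fitness_sd: float, n_features: int
) -> float:
    """Predicted overestimation for one meta-feature triple (unclipped)."""
    model._check_fitted()
    return float(
        model.predict(np.array([[original_fitness, fitness_sd, n_features]]))[0]
    )


def build_adjuster_samples(
    fold_hofs: List[SolutionSet],
    folds: Optional[FoldsData],
    obj_index: int,
) -> List[AdjusterSample]:
    """Training rows for one objective, concatenated across folds.

    Every solution in every fold's hall-of-fame front becomes one row;
    within each fold the hypervolume-derivative weights sum to 1.
    """
    samples: List[AdjusterSample] = []
    for fold_i, hof in enumerate(fold_hofs):
        if len(hof) == 0:
            continue
        F = hof.fitness_matrix()
        weights = assign_weights(F, obj_index)
        Sd = hof.sd_matrix()
        T = hof.test_fitness_matrix()
        for s_i, sol in enumerate(hof.solutions):
            samples.append(
                AdjusterSample(
                    original_fitness=float(F[s_i, obj_index]),
                    fitness_sd=float(Sd[s_i, obj_index]),
                    n_features=sol.feature_set.size,
                    overestimation=float(F[s_i, obj_index] - T[s_i, obj_index]),
                    weight=float(weights[s_i]),
                    fold=fold_i,
                    objective=obj_index,
                )
            )
    return samples


def train_adjuster(
    learner_kind: str,
    obj_index: int,
    fold_hofs: List[SolutionSet],
    folds: Optional[FoldsData] = None,
    seed: int = 0,
) -> BaseAdjuster:
    """Build samples from the fold halls-of-fame and fit one adjuster."""
    samples = build_adjuster_samples(fold_hofs, folds, obj_index)
    return fit_adjuster(learner_kind, samples, seed=seed)


def samples_to_frame(samples: Iterable[AdjusterSample]) -> pd.DataFrame:
    rows = [
        {
            "fold": s.fold,
            "objective": s.objective,
            "original_fitness": s.original_fitness,
            "sd": s.fitness_sd,
            "n_features": s.n_features,
            "overestimation": s.overestimation,
            "weight": s.weight,
        }
        for s in samples
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "fold",
            "objective",
            "original_fitness",
            "sd",
            "n_features",
            "overestimation",
            "weight",
        ],
    )


def samples_from_frame(frame: pd.DataFrame) -> List[AdjusterSample]:
    return [
        AdjusterSample(
            original_fitness=float(r.original_fitness),
            fitness_sd=float(r.sd),
            n_features=int(r.n_features),
            overestimation=float(r.overestimation),
            weight=float(r.weight),
            fold=int(r.fold),
            objective=int(r.objective),
        )
        for r in frame.itertuples(index=False)
    ]
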
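"""Fitness evaluators: inner-CV model metrics, parsimony, adjusted objectives.

Model-metric objectives train an inner learner (naive Bayes, linear SVM
or a Cox proportional-hazards model) on the selected features under
stratified k-fold cross-validation, score the pooled out-of-fold
predictions with balanced accuracy or the concordance index, and attach
a bootstrap standard deviation of that score.  The parsimony objective
(root-leanness) rewards small panels deterministically.

An adjusted objective wraps a base objective together with a trained
overestimation regressor: the reported fitness is the base fitness
minus the predicted overestimation, clipped into [0, 1].
"""

from __future__ import annotations

import logging
import math
import warnings
from typing import Callable, Optional

import numpy as np
from sklearn.base import clone
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC
from sksurv.linear_model import CoxPHSurvivalAnalysis
from sksurv.metrics import concordance_index_censored
from sksurv.util import Surv

from .core import (
    Dataset,
    FeatureSet,
    FitnessEvaluation,
    ObjectiveSpec,
    create_folds,
)

logger = logging.getLogger("dosamo")

__all__ = [
    "balanced_accuracy",
    "concordance_index",
    "root_leanness",
    "bootstrap_sd",
    "inner_cv_fitness",
    "ClassificationObjective",
    "SurvivalObjective",
    "ParsimonyObjective",
    "AdjustedObjective",
    "make_adjusted_objective",
    "CoxRiskModel",
    "make_classifier",
]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def balanced_accuracy(y_true, y_pred) -> float:
    """Mean per-class recall over the classes present in ``y_true``.

    Predicted labels outside the known classes count as errors for
    their true class.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("y_true and y_pred must be equal-length, non-empty")
    classes = np.unique(y_true)
    recalls = np.empty(len(classes))
    for c_i, c in enumerate(classes):
        in_class = y_true == c
        recalls[c_i] = np.mean(y_pred[in_class] == c)
    return float(recalls.mean())


def _balanced_accuracy_or_nan(y_true, y_pred, classes) -> float:
    """Bootstrap-resample variant: NaN when a class vanished."""
    present = np.unique(y_true)
    if len(present) < len(classes):
        return float("nan")
    return balanced_accuracy(y_true, y_pred)


def concordance_index(times, events, risk_scores) -> float:
    """Harrell's c-index: fraction of comparable pairs ordered correctly.

    Tied risk scores count 0.5.  With no comparable pair the value is
    undefined; 0.5 is returned with a warning.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    risk = np.asarray(risk_scores, dtype=float)
    if not (len(times) == len(events) == len(risk)):
        raise ValueError("times, events and risk_scores must share length")
    try:
        cindex, *_ = concordance_index_censored(events, times, risk)
    except Exception:
        logger.warning("no comparable pairs; c-index undefined, returning 0.5")
        return 0.5
    return float(cindex)


def _concordance_or_nan(y, risk) -> float:
    times, events = y
    events = np.asarray(events).astype(bool)
    try:
        cindex, *_ = concordance_index_censored(events, np.asarray(times, float), np.asarray(risk, float))
    except Exception:
        return float("nan")
    return float(cindex)


def root_leanness(feature_set, cap: int = 100) -> float:
    """Parsimony fitness ``max(0, 1 - sqrt(k / cap))`` for panel size k."""
    if cap < 1:
        raise ValueError("cap must be >= 1")
    k = feature_set.size if isinstance(feature_set, FeatureSet) else int(feature_set)
    return max(0.0, 1.0 - math.sqrt(k / cap))


# ---------------------------------------------------------------------------
# bootstrap SD of a cross-validated metric
# ---------------------------------------------------------------------------

def bootstrap_sd(
    out_of_fold_predictions: np.ndarray,
    y,
    metric: Callable,
    B: int = 100,
    seed: int = 0,
) -> float:
    """SD of ``metric`` over B bootstrap resamples of (prediction, truth).

    Pairs are resampled with replacement (n out of n) and the metric is
    recomputed per resample; resamples on which the metric is undefined
    (NaN) are redrawn, up to ``10 B`` attempts in total, then skipped.
    ``y`` may be a label array or a tuple of outcome arrays (e.g.
    (time, event)); all components are resampled jointly.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    preds = np.asarray(out_of_fold_predictions)
    y_parts = y if isinstance(y, tuple) else (y,)
    n = len(preds)
    rng = np.random.default_rng(seed)
    values = []
    attempts = 0
    while len(values) < B and attempts < 10 * B:
        attempts += 1
        idx = rng.integers(0, n, size=n)
        y_res = tuple(np.asarray(p)[idx] for p in y_parts)
        v = metric(y_res if isinstance(y, tuple) else y_res[0], preds[idx])
        if not math.isnan(v):
            values.append(v)
    if not values:
        logger.warning("all bootstrap resamples undefined; SD set to 0")
        return 0.0
    return float(np.std(values, ddof=1))


# ---------------------------------------------------------------------------
# inner learners
# ---------------------------------------------------------------------------

def make_classifier(name: str):
    """Bundled inner classifiers: Gaussian naive Bayes or linear SVM."""
    if name == "nb":
        return GaussianNB()
    if name == "svm":
        return SVC(kernel="linear", C=1.0)
    raise ValueError(f"unknown classifier {name!r} (expected 'nb' or 'svm')")


class CoxRiskModel:
    """Cox proportional-hazards risk model with a zero-risk fallback.

    Exposes ``fit(X, time, event)`` and ``predict(X)`` returning risk
    scores (higher = earlier expected event).  A failed fit (e.g. a
    singular design on a tiny fold) predicts constant zero risk.
    """

    def __init__(self, alpha: float = 0.1):
        self.alpha = alpha  # small ridge term stabilizes tiny folds
        self._model = None

    def fit(self, X, time, event):
        y = Surv.from_arrays(event=np.asarray(event).astype(bool), time=time)
        model = CoxPHSurvivalAnalysis(alpha=self.alpha)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X, y)
            self._model = model
        except Exception as exc:
            logger.warning("Cox fit failed (%s); zero-risk fallback", exc)
            self._model = None
        return self

    def predict(self, X) -> np.ndarray:
        if self._model is None:
            return np.zeros(len(X))
        return np.asarray(self._model.predict(X), dtype=float)


# ---------------------------------------------------------------------------
# inner-CV fitness
# ---------------------------------------------------------------------------

def _oof_class_predictions(
    X: np.ndarray, data: Dataset, k_inner: int, model, seed: int
) -> np.ndarray:
    folds = create_folds(data, k_inner, seed)
    preds = np.empty(data.n_samples, dtype=data.y.dtype)
    for train_idx, test_idx in folds:
        est = clone(model)
        try:
            est.fit(X[train_idx], data.y[train_idx])
            preds[test_idx] = est.predict(X[test_idx])
        except Exception as exc:
            # majority-class fallback keeps the GA running on a bad fold
            vals, counts = np.unique(data.y[train_idx], return_counts=True)
            preds[test_idx] = vals[np.argmax(counts)]
            logger.warning("classifier fit failed on a fold (%s)", exc)
    return preds


def _oof_risk_predictions(
    X: np.ndarray, data: Dataset, k_inner: int, seed: int, alpha: float
) -> np.ndarray:
    folds = create_folds(data, k_inner, seed)
    risk = np.empty(data.n_samples, dtype=float)
    for train_idx, test_idx in folds:
        model = CoxRiskModel(alpha=alpha)
        model.fit(X[train_idx], data.time[train_idx], data.event[train_idx])
        risk[test_idx] = model.predict(X[test_idx])
    return risk


def inner_cv_fitness(
    feature_set: FeatureSet,
    data: Dataset,
    model,
    k_inner: int,
    metric: Callable,
    seed: int,
    n_bootstrap: int = 100,
) -> FitnessEvaluation:
    """Classification fitness from pooled out-of-fold predictions.

    The metric is computed once on the pooled predictions of the inner
    CV (not averaged per fold), and its SD comes from bootstrapping the
    (prediction, truth) pairs.
    """
    if feature_set.size == 0:
        raise ValueError("cannot evaluate an empty feature set")
    if k_inner < 2:
        raise ValueError("k_inner must be >= 2")
    X = data.X[:, list(feature_set.indices)]
    preds = _oof_class_predictions(X, data, k_inner, model, seed)
    fitness = metric(data.y, preds)
    classes = np.unique(data.y)
    sd = bootstrap_sd(
        preds,
        data.y,
        lambda yt, yp: _balanced_accuracy_or_nan(yt, yp, classes),
        B=n_bootstrap,
        seed=seed + 1,
    )
    return FitnessEvaluation(
        fitness=float(np.clip(fitness, 0.0, 1.0)),
        sd=sd,
        n_features=feature_set.size,
    )


# ---------------------------------------------------------------------------
# objective classes
# ---------------------------------------------------------------------------

class ClassificationObjective(ObjectiveSpec):
    """Balanced accuracy of an inner classifier under inner k-fold CV."""

    kind = "model_metric"

    def __init__(
        self,
        model: str | object = "nb",
        k_inner: int = 5,
        n_bootstrap: int = 100,
        name: Optional[str] = None,
    ):
        self.model = make_classifier(model) if isinstance(model, str) else model
        self.k_inner = k_inner
        self.n_bootstrap = n_bootstrap
        self.name = name or "balanced_accuracy"

    def evaluate(self, feature_set, data, seed):
        if data.y is None:
            raise ValueError("classification objective needs class labels")
        return inner_cv_fitness(
            feature_set,
            data,
            self.model,
            self.k_inner,
            balanced_accuracy,
            seed,
            self.n_bootstrap,
        )

    def evaluate_holdout(self, feature_set, train, holdout):
        cols = list(feature_set.indices)
        est = clone(self.model)
        try:
            est.fit(train.X[:, cols], train.y)
            preds = est.predict(holdout.X[:, cols])
        except Exception as exc:
            vals, counts = np.unique(train.y, return_counts=True)
            preds = np.full(holdout.n_samples, vals[np.argmax(counts)])
            logger.warning("holdout classifier fit failed (%s)", exc)
        return float(np.clip(balanced_accuracy(holdout.y, preds), 0.0, 1.0))


class SurvivalObjective(ObjectiveSpec):
    """Concordance index of a Cox model under inner k-fold CV."""

    kind = "model_metric"

    def __init__(
        self,
        k_inner: int = 5,
        n_bootstrap: int = 100,
        alpha: float = 0.1,
        name: Optional[str] = None,
    ):
        self.k_inner = k_inner
        self.n_bootstrap = n_bootstrap
        self.alpha = alpha
        self.name = name or "c_index"

    def evaluate(self, feature_set, data, seed):
        if data.time is None:
            raise ValueError("survival objective needs (time, event)")
        if feature_set.size == 0:
            raise ValueError("cannot evaluate an empty feature set")
        if self.k_inner < 2:
            raise ValueError("k_inner must be >= 2")
        # stratify inner folds on the event indicator only
        surv_view = Dataset(
            X=data.X, time=data.time, event=data.event,
            feature_names=data.feature_names,
        )
        X = data.X[:, list(feature_set.indices)]
        risk = _oof_risk_predictions(X, surv_view, self.k_inner, seed, self.alpha)
        fitness = concordance_index(data.time, data.event, risk)
        sd = bootstrap_sd(
            risk,
            (data.time, data.event),
            _concordance_or_nan,
            B=self.n_bootstrap,
            seed=seed + 1,
        )
        return FitnessEvaluation(
            fitness=float(np.clip(fitness, 0.0, 1.0)),
            sd=sd,
            n_features=feature_set.size,
        )

    def evaluate_holdout(self, feature_set, train, holdout):
        cols = list(feature_set.indices)
        model = CoxRiskModel(alpha=self.alpha)
        model.fit(train.X[:, cols], train.time, train.event)
        risk = model.predict(holdout.X[:, cols])
        c = concordance_index(holdout.time, holdout.event, risk)
        return float(np.clip(c, 0.0, 1.0))


class ParsimonyObjective(ObjectiveSpec):
    """Root-leanness: deterministic parsimony score, SD = 0."""

    kind = "parsimony"

    def __init__(self, cap: int = 100, name: str = "root_leanness"):
        if cap < 1:
            raise ValueError("cap must be >= 1")
        self.cap = cap
        self.name = name

    def evaluate(self, feature_set, data, seed):
        return FitnessEvaluation(
            fitness=root_leanness(feature_set, self.cap),
            sd=0.0,
            n_features=feature_set.size,
        )

    def evaluate_holdout(self, feature_set, train, holdout):
        return root_leanness(feature_set, self.cap)


class AdjustedObjective(ObjectiveSpec):
    """Base objective minus the regression-predicted overestimation.

    The pipeline computes the base fitness, its SD and the panel size,
    feeds the triple to the trained adjuster, and reports
    ``clip(fitness - predicted_overestimation, 0, 1)``.  The reported
    SD stays the base SD.
    """

    def __init__(self, base: ObjectiveSpec, adjuster):
        if not getattr(adjuster, "is_fitted", False):
            raise ValueError("adjuster must be fitted before wrapping")
        self.base = base
        self.adjuster = adjuster
        self.name = base.name
        self.kind = base.kind

    def evaluate(self, feature_set, data, seed):
        ev = self.base.evaluate(feature_set, data, seed)
        over = float(
            self.adjuster.predict(
                np.array([[ev.fitness, ev.sd, ev.n_features]])
            )[0]
        )
        return FitnessEvaluation(
            fitness=float(np.clip(ev.fitness - over, 0.0, 1.0)),
            sd=ev.sd,
            n_features=ev.n_features,
        )

    def evaluate_holdout(self, feature_set, train, holdout):
        return self.base.evaluate_holdout(feature_set, train, holdout)


def make_adjusted_objective(base: ObjectiveSpec, adjuster) -> AdjustedObjective:
    return AdjustedObjective(base, adjuster)
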
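"""Synthetic omics-like data with known informative features.

The generator emulates the "many features, few samples" regime of bulk
transcriptomic cohorts: a handful of informative genes carry a
class-dependent mean shift (classification) or a linear log-hazard
effect (survival), while the remaining features are pure noise.  With
the default sizes (60 samples, 500 features, 3 informative) wrapper
selection overfits enough that inner-CV fitness estimates exceed
holdout performance on average — the overestimation the adjusters are
meant to learn.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .core import Dataset

__all__ = ["SyntheticSpec", "generate_classification", "generate_survival"]


@dataclass
class SyntheticSpec:
    """Generation settings for one synthetic dataset.

    class_separation is the between-class mean gap of an informative
    feature (in units of its within-class SD of 1); effect_size is the
    per-feature log-hazard coefficient of the survival model;
    censoring_fraction is the target fraction of censored samples.
    """

    n_samples: int = 60
    n_features: int = 500
    n_informative: int = 3
    n_classes: int = 2
    class_separation: float = 1.0
    noise_sd: float = 1.0
    effect_size: float = 1.0
    baseline_hazard: float = 0.1
    censoring_fraction: float = 0.3
    positive: bool = False  # exponentiate into log-normal-like expression
    seed: int = 0
    cohort_seed: Optional[int] = None  # fresh samples, same population

    def __post_init__(self) -> None:
        if self.n_informative > self.n_features:
            raise ValueError("n_informative must be <= n_features")
        if self.n_samples < 2 * self.n_classes:
            raise ValueError("need at least 2 samples per class")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.censoring_fraction < 1.0:
            raise ValueError("censoring_fraction must lie in [0, 1)")


def _rngs(spec: SyntheticSpec):
    """Structure stream (informative indices) is tied to ``seed`` alone, so
    a different ``cohort_seed`` draws new samples from the same population."""
    struct = np.random.default_rng([spec.seed, 1])
    cohort = spec.seed if spec.cohort_seed is None else spec.cohort_seed
    return struct, np.random.default_rng([cohort, 2])


def _informative_indices(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    return np.sort(rng.choice(spec.n_features, size=spec.n_informative, replace=False))


def generate_classification(spec: SyntheticSpec) -> Tuple[Dataset, np.ndarray]:
    """Class-shift Gaussian data; returns (dataset, informative indices).

    Informative features have class ``c`` mean ``c * class_separation``
    and unit SD; all other features are ``N(0, noise_sd)``.
    """
    struct_rng, rng = _rngs(spec)
    n, p = spec.n_samples, spec.n_features
    y = rng.permutation(np.arange(n) % spec.n_classes)
    X = rng.normal(0.0, spec.noise_sd, size=(n, p))
    informative = _informative_indices(spec, struct_rng)
    for j in informative:
        X[:, j] = rng.normal(y * spec.class_separation, 1.0)
    if spec.positive:
        X = np.exp(X)
    data = Dataset(X=X, y=y)
    return data, informative


def _calibrate_censoring(times: np.ndarray, target_event_fraction: float) -> float:
    """Upper bound c of Uniform(0, c) censoring so that the expected
    event fraction matches the target (solved on the drawn times)."""
    def event_fraction(c: float) -> float:
        return float(np.mean(np.maximum(0.0, 1.0 - times / c)))

    lo, hi = times.min() * 1e-6 + 1e-12, times.max() * 1e6 + 1.0
    for _ in range(200):
        mid = np.sqrt(lo * hi)  # bisection in log space
        if event_fraction(mid) < target_event_fraction:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def generate_survival(spec: SyntheticSpec) -> Tuple[Dataset, np.ndarray]:
    """Exponential survival times with a Cox-compatible linear log-hazard.

    Event times are exponential with rate
    ``baseline_hazard * exp(sum_j beta_j x_j)`` over the informative
    features (all ``beta_j = effect_size``); censoring times are uniform
    with their range calibrated so the expected censored fraction
    matches ``censoring_fraction``.
    """
    struct_rng, rng = _rngs(spec)
    n, p = spec.n_samples, spec.n_features
    X = rng.normal(0.0, 1.0, size=(n, p))
    informative = _informative_indices(spec, struct_rng)
    lp = X[:, informative].sum(axis=1) * spec.effect_size
    rate = spec.baseline_hazard * np.exp(lp)
    T = rng.exponential(1.0 / rate)
    if spec.censoring_fraction == 0.0:
        time, event = T, np.ones(n, dtype=int)
    else:
        c = _calibrate_censoring(T, 1.0 - spec.censoring_fraction)
        U = rng.uniform(0.0, c, size=n)
        event = (T <= U).astype(int)
        time = np.minimum(T, U)
    if spec.positive:
        X = np.exp(X)
    data = Dataset(X=X, time=time, event=event)
    return data, informative
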
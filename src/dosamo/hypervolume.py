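"""Hypervolume machinery and set-level estimation-error metrics.

All fitness values are maximized scores in ``[0, 1]`` and the
hypervolume (HV) reference point is fixed at the origin, so the HV of a
solution set is the measure of the union of the axis-aligned boxes
``[0, x_i1] x ... x [0, x_im]``.

Besides the HV itself this module provides:

* exact right partial derivatives of the HV with respect to every
  fitness entry — the (m-1)-dimensional measure of the exclusive face of
  each solution's box, used to weight adjuster training samples by how
  much a solution actually contributes to the front;
* the cross hypervolume (CHV), an HV-like aggregate where each
  coordinate mixes the train-based estimate with the test-measured value
  through a user-supplied cross function ``v`` with ``v(x, x) = x``;
* the multi-objective performance error (MOPE), the absolute difference
  between the train HV and the CHV;
* the Pareto delta, the HV-derivative-weighted mean absolute train-test
  fitness discrepancy, averaged over objectives.
"""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np

from .core import nondominated_front

__all__ = [
    "hypervolume",
    "hv_gradient",
    "cross_hypervolume",
    "default_cross_function",
    "mope",
    "pareto_delta",
    "assign_weights",
]

CrossFunction = Callable[[float, float], float]


def _validate_unit(P: np.ndarray, name: str = "points") -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if P.ndim != 2:
        raise ValueError(f"{name} must be a 2-D matrix")
    if P.size and (not np.all(np.isfinite(P)) or P.min() < 0.0 or P.max() > 1.0):
        raise ValueError(f"{name} entries must lie in [0, 1]; clip upstream")
    return P


def _hv(P: np.ndarray) -> float:
    """Recursive dimension-sweep hypervolume; exact for small n, m <= 4."""
    n, m = P.shape
    if n == 0:
        return 0.0
    if m == 1:
        return float(P.max())
    if m == 2:
        # sort by x descending; accumulate staircase area
        order = np.argsort(-P[:, 0], kind="stable")
        area = 0.0
        best_y = 0.0
        prev_x = None
        for i in order:
            x, y = P[i]
            if y > best_y:
                if prev_x is None:
                    area += x * y
                else:
                    area += x * (y - best_y)
                best_y = y
                prev_x = x
        return area
    # m >= 3: sweep slabs along the last coordinate
    levels = np.unique(P[:, -1])[::-1]
    vol = 0.0
    for t, z in enumerate(levels):
        z_next = levels[t + 1] if t + 1 < len(levels) else 0.0
        if z == 0.0:
            break
        active = P[P[:, -1] >= z][:, :-1]
        vol += (z - z_next) * _hv(active)
    return vol


def hypervolume(points: np.ndarray) -> float:
    """HV of a set of [0,1]^m fitness rows with the origin as reference.

    Rows need not be mutually non-dominated; dominated rows simply add
    no volume.  Empty input has volume 0.
    """
    P = _validate_unit(points)
    if P.size == 0:
        return 0.0
    return _hv(P)


def hv_gradient(points: np.ndarray) -> np.ndarray:
    """Exact right partial derivatives ``dHV/dx_ij`` of the hypervolume.

    Entry (i, j) is the (m-1)-dimensional measure of the part of box
    ``i``'s face at coordinate ``x_ij`` not covered by any other box —
    the rate at which the HV grows when ``x_ij`` is increased.  Rows
    that are dominated, or exact duplicates of a lower-index row, get
    all-zero rows (their box contributes no exclusive volume).
    """
    P = _validate_unit(points)
    n, m = P.shape
    G = np.zeros((n, m))
    if n == 0:
        return G
    if m == 1:
        # HV is the max; only the (first) maximal point moves it
        G[int(np.argmax(P[:, 0])), 0] = 1.0
        return G
    kept = sorted(nondominated_front(P))
    for i in kept:
        for j in range(m):
            reduced_i = np.delete(P[i], j)
            face = float(np.prod(reduced_i))
            if face == 0.0:
                continue
            comp = [p for p in kept if p != i and P[p, j] > P[i, j]]
            if comp:
                # intersection of each competitor box with box i's face
                clipped = np.minimum(np.delete(P[comp], j, axis=1), reduced_i)
                covered = _hv(clipped)
            else:
                covered = 0.0
            G[i, j] = face - covered
    return G


def default_cross_function(train_value: float, test_value: float) -> float:
    """Default ``v``: take the test value, clipped into [0, 1]."""
    return float(min(1.0, max(0.0, test_value)))


def cross_hypervolume(
    X: np.ndarray,
    X_test: np.ndarray,
    cross_function: Optional[CrossFunction] = None,
) -> float:
    """CHV: HV of the matrix with entries ``v(x_ij, x'_ij)``.

    ``X`` holds train-estimated fitness (which decided what entered the
    front), ``X_test`` the fitness measured on new samples.  Any ``v``
    with ``v(x, x) = x`` makes the CHV coincide with the HV when test
    equals train.
    """
    X = _validate_unit(X, "X")
    Xp = _validate_unit(X_test, "X_test")
    if X.shape != Xp.shape:
        raise ValueError("train and test fitness matrices must share shape")
    if cross_function is None:
        V = np.clip(Xp, 0.0, 1.0)
    else:
        V = np.empty_like(X)
        for i in range(X.shape[0]):
            for j in range(X.shape[1]):
                V[i, j] = cross_function(X[i, j], Xp[i, j])
    return hypervolume(V)


def mope(
    X: np.ndarray,
    X_test: np.ndarray,
    cross_function: Optional[CrossFunction] = None,
) -> float:
    """Multi-objective performance error: ``|HV(X) - CHV(X, X')|``."""
    return abs(hypervolume(X) - cross_hypervolume(X, X_test, cross_function))


def pareto_delta(X: np.ndarray, X_test: np.ndarray) -> float:
    """HV-derivative-weighted mean absolute train-test discrepancy.

    ``(1/m) * sum_j sum_i |x_ij - x'_ij| * dHV/dx_ij`` with the partial
    derivatives taken on the train matrix.  Defined as exactly 0 when
    there are zero solutions or zero objectives.
    """
    X = _validate_unit(X, "X")
    Xp = _validate_unit(X_test, "X_test")
    if X.shape != Xp.shape:
        raise ValueError("train and test fitness matrices must share shape")
    n, m = X.shape
    if n == 0 or m == 0:
        return 0.0
    G = hv_gradient(X)
    return float(np.sum(np.abs(X - Xp) * G) / m)


def assign_weights(X: np.ndarray, obj_index: int) -> np.ndarray:
    """Adjuster-sample weights for one fold and one objective.

    Proportional to column ``obj_index`` of the HV gradient of the
    fold's train-fitness matrix, rescaled to sum to 1.  When every
    solution has zero partial derivative for this objective the weights
    fall back to uniform.
    """
    X = _validate_unit(X, "X")
    n = X.shape[0]
    if n == 0:
        return np.zeros(0)
    col = hv_gradient(X)[:, obj_index]
    total = col.sum()
    if total <= 0.0:
        return np.full(n, 1.0 / n)
    return col / total
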
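"""Linear soft-margin support vector machine, implemented from first principles.

The decoder is the standard hinge-loss SVM

    minimize  (1/2)||W||^2 + C * sum_i max(0, 1 - y_i (W.x_i + Z))

over weights ``W`` and an *unregularized* bias ``Z``, with ``C = 10`` by
default and features in raw percent-signal-change units (no
standardization).  The decision function is ``Y = W.X + Z``: positive Y is
classified painful, negative non-painful, and ``|Y| / ||W||`` (the
geometric distance to the separating hyperplane) serves as classification
confidence.

Training solves the dual quadratic program with sequential minimal
optimization (SMO) over the precomputed linear kernel, using second-order
working-set selection and the maximal-violation stopping rule.  The problem
is convex, the solver takes no random steps, so training is deterministic
given its inputs.  ``precompute_kernel``/``train_from_kernel`` let callers
that retrain many times under relabelings (permutation tests) reuse the
Gram matrix.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

DEFAULT_C = 10.0
DEFAULT_TOL = 1e-8
_TAU = 1e-12


class SVMError(ValueError):
    pass


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class LinearModel:
    """Trained linear SVM: weights W, bias Z and the regularization C."""

    weights: np.ndarray
    bias: float
    c_param: float = DEFAULT_C

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        self.bias = float(self.bias)

    @property
    def n_features(self) -> int:
        return self.weights.size

    @property
    def weight_norm(self) -> float:
        return float(np.linalg.norm(self.weights))

    def save(self, path_prefix) -> None:
        """Serialize as a JSON metadata file plus a binary weight vector."""
        path_prefix = Path(path_prefix)
        np.save(path_prefix.with_suffix(".weights.npy"), self.weights)
        meta = {"bias": self.bias, "c_param": self.c_param, "n_features": self.n_features}
        path_prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path_prefix) -> "LinearModel":
        path_prefix = Path(path_prefix)
        meta = json.loads(path_prefix.with_suffix(".json").read_text())
        weights = np.load(path_prefix.with_suffix(".weights.npy"))
        return cls(weights=weights, bias=meta["bias"], c_param=meta["c_param"])


@dataclass(frozen=True)
class DecisionResult:
    """Signed decision value and derived classification for one example."""

    decision_value: float          # Y = W.X + Z
    predicted_label: int           # +1 painful, -1 nonpainful; Y == 0 -> -1
    distance: float                # geometric |Y| / ||W||
    distance_functional: float     # raw |Y|


def _validate_training_input(X: np.ndarray, y: np.ndarray) -> None:
    if X.ndim != 2:
        raise SVMError("matrix must be 2D (examples x features)")
    if y.shape != (X.shape[0],):
        raise SVMError("labels must align with matrix rows")
    if not np.isfinite(X).all():
        raise SVMError("matrix contains NaN or infinite values")
    classes = np.unique(y)
    if not np.array_equal(classes, [-1, 1]):
        raise SVMError(f"need both classes (+1/-1) present, got labels {classes}")
    if np.all(X == X[0]):
        raise SVMError("degenerate input: all example rows are identical")


def precompute_kernel(X: np.ndarray) -> np.ndarray:
    """Linear Gram matrix X X^T for reuse across relabeled retrainings."""
    X = np.asarray(X, dtype=float)
    return X @ X.T


def _solve_smo(
    K: np.ndarray, y: np.ndarray, C: float, tol: float, max_iter: int
) -> tuple[np.ndarray, float]:
    """SMO on the dual: min (1/2)a'Qa - e'a, 0 <= a <= C, y'a = 0.

    Returns (alpha, bias).  Second-order working-set selection per pair;
    stops when the maximal KKT violation falls below ``tol``.
    """
    n = y.size
    yf = y.astype(float)
    Q = (yf[:, None] * yf[None, :]) * K
    Kdiag = np.diag(K).copy()
    alpha = np.zeros(n)
    G = -np.ones(n)  # gradient of the dual objective at alpha = 0

    pos = yf > 0
    it = 0
    for it in range(max_iter):
        myG = -yf * G  # bias candidates; m - M is the KKT violation
        up = (pos & (alpha < C)) | (~pos & (alpha > 0))
        low = (pos & (alpha > 0)) | (~pos & (alpha < C))
        if not up.any() or not low.any():
            break
        i = int(np.argmax(np.where(up, myG, -np.inf)))
        gmax = myG[i]
        low_vals = np.where(low, myG, np.inf)
        gmin = float(low_vals.min())
        if gmax - gmin <= tol:
            break

        # second-order selection of j: maximal decrease of the dual objective
        Ki = K[i]
        grad_diff = gmax - myG
        cand = low & (grad_diff > 0)
        a = Kdiag[i] + Kdiag - 2.0 * Ki
        a = np.where(a > 0, a, _TAU)
        obj_diff = np.where(cand, -(grad_diff**2) / a, np.inf)
        j = int(np.argmin(obj_diff))

        old_i, old_j = alpha[i], alpha[j]
        quad = Kdiag[i] + Kdiag[j] - 2.0 * K[i, j]
        if quad <= 0:
            quad = _TAU
        if yf[i] != yf[j]:
            delta = (-G[i] - G[j]) / quad
            diff = alpha[i] - alpha[j]
            alpha[i] += delta
            alpha[j] += delta
            if diff > 0:
                if alpha[j] < 0:
                    alpha[j] = 0.0
                    alpha[i] = diff
            else:
                if alpha[i] < 0:
                    alpha[i] = 0.0
                    alpha[j] = -diff
            if diff > 0:
                if alpha[i] > C:
                    alpha[i] = C
                    alpha[j] = C - diff
            else:
                if alpha[j] > C:
                    alpha[j] = C
                    alpha[i] = C + diff
        else:
            delta = (G[i] - G[j]) / quad
            total = alpha[i] + alpha[j]
            alpha[i] -= delta
            alpha[j] += delta
            if total > C:
                if alpha[i] > C:
                    alpha[i] = C
                    alpha[j] = total - C
                if alpha[j] > C:
                    alpha[j] = C
                    alpha[i] = total - C
            else:
                if alpha[j] < 0:
                    alpha[j] = 0.0
                    alpha[i] = total
                if alpha[i] < 0:
                    alpha[i] = 0.0
                    alpha[j] = total

        G += Q[:, i] * (alpha[i] - old_i) + Q[:, j] * (alpha[j] - old_j)
    else:
        warnings.warn(
            f"SMO hit the iteration cap ({max_iter}) before reaching tol={tol}",
            ConvergenceWarning,
            stacklevel=2,
        )

    # bias from the KKT conditions: Z = -y_t G_t at free support vectors
    myG = -yf * G
    free = (alpha > _TAU) & (alpha < C - _TAU)
    if free.any():
        bias = float(myG[free].mean())
    else:
        up = (pos & (alpha < C)) | (~pos & (alpha > 0))
        low = (pos & (alpha > 0)) | (~pos & (alpha < C))
        hi = float(np.max(np.where(up, myG, -np.inf))) if up.any() else 0.0
        lo = float(np.min(np.where(low, myG, np.inf))) if low.any() else 0.0
        bias = (hi + lo) / 2.0
    return alpha, bias


def train_from_kernel(
    K: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    c_param: float = DEFAULT_C,
    tol: float = DEFAULT_TOL,
    max_iter: int = 500_000,
) -> LinearModel:
    """Train given a precomputed Gram matrix (fast path for permutations)."""
    y = np.asarray(y)
    alpha, bias = _solve_smo(K, y, float(c_param), tol, max_iter)
    weights = (alpha * y) @ X
    return LinearModel(weights=weights, bias=bias, c_param=float(c_param))


def train(
    matrix: np.ndarray,
    labels: np.ndarray,
    c_param: float = DEFAULT_C,
    seed: int | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = 500_000,
) -> LinearModel:
    """Train the linear SVM on raw percent-signal-change features.

    The optimization is deterministic (convex QP, deterministic pivoting);
    ``seed`` is accepted for interface uniformity but unused.

    Raises
    ------
    SVMError
        If only one class is present, the matrix contains NaN, or all
        example rows are identical.
    """
    del seed  # deterministic solver; kept for a uniform stage interface
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(labels)
    _validate_training_input(X, y)
    return train_from_kernel(precompute_kernel(X), X, y, c_param, tol, max_iter)


def decide(model: LinearModel, example_row: np.ndarray) -> DecisionResult:
    """Decision value, label and hyperplane distances for one example.

    A tie at Y = 0 is classified non-painful: the absence of positive
    evidence is not called pain.
    """
    x = np.asarray(example_row, dtype=float).ravel()
    if x.size != model.n_features:
        raise SVMError(f"example has {x.size} features, model expects {model.n_features}")
    norm = model.weight_norm
    if norm == 0:
        raise SVMError("model has a zero weight vector; distances are undefined")
    y_val = float(model.weights @ x + model.bias)
    return DecisionResult(
        decision_value=y_val,
        predicted_label=1 if y_val > 0 else -1,
        distance=abs(y_val) / norm,
        distance_functional=abs(y_val),
    )


def decide_batch(model: LinearModel, matrix: np.ndarray) -> list[DecisionResult]:
    """Vectorized :func:`decide` over the rows of a matrix."""
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise SVMError(f"matrix shape {X.shape} incompatible with {model.n_features} features")
    norm = model.weight_norm
    if norm == 0:
        raise SVMError("model has a zero weight vector; distances are undefined")
    y_vals = X @ model.weights + model.bias
    return [
        DecisionResult(
            decision_value=float(v),
            predicted_label=1 if v > 0 else -1,
            distance=abs(float(v)) / norm,
            distance_functional=abs(float(v)),
        )
        for v in y_vals
    ]


def objective(model: LinearModel, matrix: np.ndarray, labels: np.ndarray) -> float:
    """Primal objective (1/2)||W||^2 + C * sum hinge at the given model."""
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(labels, dtype=float)
    margins = y * (X @ model.weights + model.bias)
    hinge = np.maximum(0.0, 1.0 - margins)
    return 0.5 * float(model.weights @ model.weights) + model.c_param * float(hinge.sum())
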
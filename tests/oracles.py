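"""Independent oracles used to check the implementation by a second route.

These deliberately avoid the package's own solvers: the SVM oracle is a
generic constrained QP (SLSQP on the primal with slack variables), the
sphere oracle a brute-force integer-offset enumeration, and the 1-D
classifier oracle an exhaustive threshold search.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def qp_primal_objective(X: np.ndarray, y: np.ndarray, C: float) -> float:
    """Minimum of (1/2)||w||^2 + C*sum(xi) s.t. y_i(w.x_i+z) >= 1 - xi, xi >= 0.

    Solved as a generic constrained program over (w, z, xi) — independent of
    the package's SMO path.
    """
    n, d = X.shape

    def fun(v):
        w, xi = v[:d], v[d + 1:]
        return 0.5 * w @ w + C * xi.sum()

    def jac(v):
        g = np.zeros_like(v)
        g[:d] = v[:d]
        g[d + 1:] = C
        return g

    cons = [
        {
            "type": "ineq",
            "fun": lambda v, i=i: y[i] * (X[i] @ v[:d] + v[d]) - 1 + v[d + 1 + i],
            "jac": lambda v, i=i: np.r_[y[i] * X[i], y[i], np.eye(n)[i]],
        }
        for i in range(n)
    ]
    bounds = [(None, None)] * (d + 1) + [(0, None)] * n
    v0 = np.zeros(d + 1 + n)
    v0[d + 1:] = 1.0
    res = minimize(
        fun, v0, jac=jac, constraints=cons, bounds=bounds, method="SLSQP",
        options={"maxiter": 1000, "ftol": 1e-14},
    )
    return float(res.fun)


def brute_sphere_count(radius_mm: float, voxel_mm: float) -> int:
    """Voxels whose center lies within radius of a voxel-center origin."""
    r = int(np.ceil(radius_mm / voxel_mm))
    count = 0
    for i in range(-r, r + 1):
        for j in range(-r, r + 1):
            for k in range(-r, r + 1):
                if voxel_mm**2 * (i * i + j * j + k * k) <= radius_mm**2:
                    count += 1
    return count


def best_threshold_predictions(x_train, y_train, x_test) -> np.ndarray:
    """Exhaustive 1-D threshold rule: pick the cut (and direction) with the
    fewest training errors, midpoints of sorted values as candidates."""
    x_train = np.asarray(x_train, float).ravel()
    y_train = np.asarray(y_train)
    xs = np.sort(np.unique(x_train))
    cuts = np.r_[xs[0] - 1.0, (xs[:-1] + xs[1:]) / 2.0, xs[-1] + 1.0]
    best = None
    for cut in cuts:
        for sign in (1, -1):
            pred = np.where(sign * (x_train - cut) > 0, 1, -1)
            err = np.sum(pred != y_train)
            if best is None or err < best[0]:
                best = (err, cut, sign)
    _, cut, sign = best
    return np.where(sign * (np.asarray(x_test, float).ravel() - cut) > 0, 1, -1)
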
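"""Independent reference implementations used only as test oracles.

These deliberately avoid the library code paths they are checked against:
the DFT oracle is a direct O(N^2) summation, the interpolation oracle is a
scalar monotone (Fritsch-Carlson style) Hermite scheme, and the SVM oracle
solves the small dual QP directly.
"""

from __future__ import annotations

import cmath
import math

import numpy as np
from scipy.optimize import minimize


def dft_bruteforce(x) -> np.ndarray:
    """Direct summation of X_k = sum_n x_n * exp(-2*pi*i*k*n/N)."""
    x = list(map(float, x))
    n = len(x)
    out = []
    for k in range(n):
        acc = 0j
        for i, value in enumerate(x):
            acc += value * cmath.exp(-2j * cmath.pi * k * i / n)
        out.append(acc)
    return np.array(out)


def _edge_slope(h0: float, h1: float, d0: float, d1: float) -> float:
    """One-sided three-point derivative with monotonicity clamping."""
    m = ((2.0 * h0 + h1) * d0 - h0 * d1) / (h0 + h1)
    if m * d0 <= 0.0:
        return 0.0
    if d0 * d1 < 0.0 and abs(m) > 3.0 * abs(d0):
        return 3.0 * d0
    return m


def monotone_hermite_slopes(x, y) -> list[float]:
    """Shape-preserving derivative estimates (weighted-harmonic-mean rule)."""
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    h = [x[i + 1] - x[i] for i in range(n - 1)]
    delta = [(y[i + 1] - y[i]) / h[i] for i in range(n - 1)]
    slopes = [0.0] * n
    slopes[0] = _edge_slope(h[0], h[1], delta[0], delta[1])
    slopes[-1] = _edge_slope(h[-1], h[-2], delta[-1], delta[-2])
    for i in range(1, n - 1):
        if delta[i - 1] * delta[i] <= 0.0:
            slopes[i] = 0.0
        else:
            w1 = 2.0 * h[i] + h[i - 1]
            w2 = h[i] + 2.0 * h[i - 1]
            slopes[i] = (w1 + w2) / (w1 / delta[i - 1] + w2 / delta[i])
    return slopes


def monotone_hermite_interpolate(x, y, x_new: float) -> float:
    """Evaluate the monotone piecewise cubic Hermite interpolant at one point."""
    x = list(map(float, x))
    y = list(map(float, y))
    slopes = monotone_hermite_slopes(x, y)
    # locate the bracketing interval
    idx = max(i for i in range(len(x) - 1) if x[i] <= x_new)
    h = x[idx + 1] - x[idx]
    t = (x_new - x[idx]) / h
    h00 = (1 + 2 * t) * (1 - t) ** 2
    h10 = t * (1 - t) ** 2
    h01 = t**2 * (3 - 2 * t)
    h11 = t**2 * (t - 1)
    return (
        h00 * y[idx]
        + h10 * h * slopes[idx]
        + h01 * y[idx + 1]
        + h11 * h * slopes[idx + 1]
    )


def svm_dual_solve(X, y, C: float, gamma: float):
    """Solve the soft-margin RBF-SVM dual QP; returns (alphas, bias).

    maximize sum(a) - 0.5 * a^T (y y^T * K) a  s.t.  0 <= a <= C, a.y = 0
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)  # labels in {-1, +1}
    n = X.shape[0]
    sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    K = np.exp(-gamma * sq)
    Q = (y[:, None] * y[None, :]) * K

    def objective(a):
        return 0.5 * a @ Q @ a - a.sum()

    def gradient(a):
        return Q @ a - np.ones(n)

    result = minimize(
        objective,
        x0=np.full(n, C / 2.0),
        jac=gradient,
        bounds=[(0.0, C)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}],
        method="SLSQP",
        options={"maxiter": 1000, "ftol": 1e-12},
    )
    assert result.success, result.message
    alphas = result.x
    free = (alphas > 1e-6) & (alphas < C - 1e-6)
    if not free.any():  # fall back to all support vectors
        free = alphas > 1e-6
    bias = float(np.mean([y[i] - (alphas * y) @ K[:, i] for i in np.flatnonzero(free)]))
    return alphas, bias


def svm_dual_decision(X_train, y_train, alphas, bias, gamma, X_eval) -> np.ndarray:
    X_train = np.asarray(X_train, dtype=float)
    X_eval = np.atleast_2d(np.asarray(X_eval, dtype=float))
    sq = ((X_eval[:, None, :] - X_train[None, :, :]) ** 2).sum(axis=2)
    K = np.exp(-gamma * sq)
    return K @ (alphas * np.asarray(y_train, dtype=float)) + bias
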
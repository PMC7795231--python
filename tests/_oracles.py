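"""Independent brute-force oracle for the soft-margin RBF SVM dual.

Solves  max_λ Σλ_i − ½ λᵀQλ  s.t. Σλ_i y_i = 0, 0 ≤ λ_i ≤ C  with
Q_ij = y_i y_j K(x_i, x_j) by exhaustive active-set enumeration: every
assignment of each λ_i to {lower bound, upper bound, free} is tried, the
KKT stationarity system is solved for the free variables, and feasible KKT
points are collected (for a concave QP any feasible KKT point is optimal;
the best objective is returned to be safe against round-off).

Deliberately independent of the package's SVM path: no scikit-learn, no
shared kernel code.
"""

from __future__ import annotations

import itertools

import numpy as np


def rbf_gram(X: np.ndarray, gamma: float) -> np.ndarray:
    d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
    return np.exp(-gamma * d2)


def solve_dual_bruteforce(
    X: np.ndarray, y: np.ndarray, C: float, gamma: float
) -> tuple[np.ndarray, float]:
    """Return (λ, b) for the dual; X is (n,d), y in {+1,-1}, n <= ~6."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    K = rbf_gram(X, gamma)
    Q = np.outer(y, y) * K
    tol = 1e-9

    best_obj, best_lam = -np.inf, None
    for assignment in itertools.product((0, 1, 2), repeat=n):  # 0=at 0, 1=at C, 2=free
        lam = np.zeros(n)
        upper = [i for i, a in enumerate(assignment) if a == 1]
        free = [i for i, a in enumerate(assignment) if a == 2]
        lam[upper] = C
        if free:
            # stationarity on free set: Q_FF λ_F + μ y_F = 1 − Q_FU·C
            # equality: y_Fᵀ λ_F = −C Σ_U y_U
            m = len(free)
            A = np.zeros((m + 1, m + 1))
            A[:m, :m] = Q[np.ix_(free, free)]
            A[:m, m] = y[free]
            A[m, :m] = y[free]
            rhs = np.zeros(m + 1)
            rhs[:m] = 1.0 - Q[np.ix_(free, upper)].sum(axis=1) * C if upper else 1.0
            rhs[m] = -C * y[upper].sum() if upper else 0.0
            try:
                sol = np.linalg.solve(A, rhs)
            except np.linalg.LinAlgError:
                continue
            lam[free] = sol[:m]
            mu = sol[m]
            if np.any(lam[free] < -tol) or np.any(lam[free] > C + tol):
                continue
            lam[free] = np.clip(lam[free], 0.0, C)
        else:
            if abs(np.dot(y, lam)) > tol * max(1.0, C):
                continue
            mu = None
        grad = 1.0 - Q @ lam  # dL/dλ_i (before equality multiplier)
        if mu is None:
            # choose μ minimising KKT violation: feasible iff there exists μ with
            # grad_i − μ y_i ≤ 0 for λ_i = 0 and ≥ 0 for λ_i = C
            lo, hi = -np.inf, np.inf
            for i in range(n):
                if lam[i] <= tol:  # need grad_i ≤ μ y_i
                    if y[i] > 0:
                        lo = max(lo, grad[i])
                    else:
                        hi = min(hi, -grad[i])
                else:  # at C: need grad_i ≥ μ y_i
                    if y[i] > 0:
                        hi = min(hi, grad[i])
                    else:
                        lo = max(lo, -grad[i])
            if lo > hi + tol:
                continue
            mu = (max(lo, min(hi, 0.0)) if np.isfinite(lo) or np.isfinite(hi) else 0.0)
            if np.isfinite(lo) and np.isfinite(hi):
                mu = 0.5 * (lo + hi)
        ok = True
        for i in range(n):
            r = grad[i] - mu * y[i]
            if lam[i] <= tol and r > 1e-7:
                ok = False
                break
            if lam[i] >= C - tol and r < -1e-7:
                ok = False
                break
            if tol < lam[i] < C - tol and abs(r) > 1e-7:
                ok = False
                break
        if not ok:
            continue
        obj = lam.sum() - 0.5 * lam @ Q @ lam
        if obj > best_obj + 1e-12:
            best_obj, best_lam = obj, lam.copy()
    if best_lam is None:
        raise RuntimeError("no feasible KKT point found")
    return best_lam, _bias(best_lam, X, y, K, C)


def _bias(lam: np.ndarray, X: np.ndarray, y: np.ndarray, K: np.ndarray, C: float) -> float:
    tol = 1e-7
    f_wo_b = (lam * y) @ K  # Σ λ_j y_j K(x_j, x_i)
    E = y - f_wo_b
    free = (lam > tol) & (lam < C - tol)
    if np.any(free):
        return float(E[free].mean())
    # no free support vector: b lies in an interval; take its midpoint
    lo, hi = -np.inf, np.inf
    for i in range(len(y)):
        if (y[i] > 0 and lam[i] >= C - tol) or (y[i] < 0 and lam[i] <= tol):
            lo = max(lo, E[i])
        if (y[i] > 0 and lam[i] <= tol) or (y[i] < 0 and lam[i] >= C - tol):
            hi = min(hi, E[i])
    if not np.isfinite(lo):
        return float(hi)
    if not np.isfinite(hi):
        return float(lo)
    return float(0.5 * (lo + hi))


def decision_values(
    lam: np.ndarray, b: float, X: np.ndarray, y: np.ndarray, probes: np.ndarray,
    gamma: float,
) -> np.ndarray:
    d2 = np.sum((probes[:, None, :] - X[None, :, :]) ** 2, axis=-1)
    return np.exp(-gamma * d2) @ (lam * y) + b
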
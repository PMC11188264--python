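"""Independent brute-force oracles used to cross-check the implementation.

Each oracle takes a deliberately different route from the production code:
pairwise-slope hull construction, dense linear solves, covariance
eigendecompositions, exhaustive enumeration and double loops.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_force_lower_hull(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """O(n^2) lower-hull vertex indices by the pairwise-slope definition.

    A point i is a lower-hull vertex iff no chord between two other points
    passes strictly below it ... equivalently, walking from the leftmost
    point, the next vertex after i is the point with the minimal slope from
    i (ties broken by the farthest point, which drops collinear interior
    points).
    """
    n = len(x)
    hull = [0]
    i = 0
    while i < n - 1:
        best, best_slope = None, math.inf
        for j in range(i + 1, n):
            slope = (y[j] - y[i]) / (x[j] - x[i])
            if slope < best_slope - 1e-15 or (
                    abs(slope - best_slope) <= 1e-15 and best is not None
                    and x[j] > x[best]):
                best, best_slope = j, slope
        hull.append(best)
        i = best
    return np.asarray(hull, dtype=int)


def dense_als_solve(y: np.ndarray, w: np.ndarray, lam: float) -> np.ndarray:
    """Direct dense solve of (W + lam * D2'D2) z = W y."""
    n = len(y)
    D = np.zeros((n - 2, n))
    for i in range(n - 2):
        D[i, i], D[i, i + 1], D[i, i + 2] = 1.0, -2.0, 1.0
    A = np.diag(w) + lam * D.T @ D
    return np.linalg.solve(A, w * y)


def covariance_eigen_pca(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(explained variance fractions, loadings) from the covariance
    eigendecomposition (descending)."""
    Xc = X - X.mean(axis=0)
    C = Xc.T @ Xc
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    vals = np.clip(vals, 0.0, None)
    return vals / vals.sum(), vecs.T


def exhaustive_window_max(cube: np.ndarray, wavenumbers: np.ndarray,
                          lo: float, hi: float) -> np.ndarray:
    """Per-pixel window maximum by an explicit double loop over pixels."""
    ny, nx, _ = cube.shape
    out = np.empty((ny, nx))
    for iy in range(ny):
        for ix in range(nx):
            best = -math.inf
            for k, w in enumerate(wavenumbers):
                if lo <= w <= hi and cube[iy, ix, k] > best:
                    best = cube[iy, ix, k]
            out[iy, ix] = best
    return out


def exact_ranksum_p(xa: np.ndarray, xb: np.ndarray) -> float:
    """Two-sided exact rank-sum p-value by full enumeration of all
    C(n+m, n) group assignments of the pooled (tie-free) sample."""
    pooled = np.concatenate([xa, xb])
    n, m = len(xa), len(xb)
    ranks = pooled.argsort().argsort() + 1  # tie-free by construction
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    center = n * m / 2
    total = 0
    extreme = 0
    for comb in itertools.combinations(range(n + m), n):
        u = ranks[list(comb)].sum() - n * (n + 1) / 2
        total += 1
        if abs(u - center) >= abs(u_obs - center) - 1e-12:
            extreme += 1
    return extreme / total
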
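"""Penalized regression spline bases.

``cyclic_spline_basis`` builds a cyclic cubic regression spline on the
12-month circle: the spline is parameterised by its values at k-1 unique
knots, with value, first and second derivative continuous across the wrap
(December -> January), and the penalty is the integrated squared second
derivative. Construction follows the standard cyclic natural-cubic-spline
algebra: with knot gaps h_j, banded cyclic matrices B and D relate knot
second derivatives m to knot values f via B m = D f, giving penalty
S = D' B^{-1} D and an explicit cardinal basis.

``bspline_basis`` is a plain cubic B-spline basis for the long-term trend,
with its second-derivative penalty computed by exact quadrature (second
derivatives of cubics are piecewise linear, so Simpson's rule on each
inter-knot interval is exact).
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import BSpline


def _cyclic_BD(knots: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cyclic tridiagonal B and D for knot values -> second derivatives."""
    h = np.diff(knots)  # k-1 gaps, gap j spans [knot_j, knot_{j+1}]
    K = len(h)  # number of unique knots
    B = np.zeros((K, K))
    D = np.zeros((K, K))
    for i in range(K):
        hm = h[i - 1]  # gap ending at knot i (wraps)
        hp = h[i]  # gap starting at knot i
        B[i, i] = (hm + hp) / 3.0
        B[i, (i + 1) % K] += hp / 6.0
        B[i, (i - 1) % K] += hm / 6.0
        D[i, i] = -1.0 / hm - 1.0 / hp
        D[i, (i + 1) % K] += 1.0 / hp
        D[i, (i - 1) % K] += 1.0 / hm
    return B, D


def cyclic_spline_basis(
    x: np.ndarray, k: int = 8, period: float = 12.0
) -> tuple[np.ndarray, np.ndarray]:
    """Cyclic cubic regression spline basis and wiggliness penalty.

    Parameters
    ----------
    x : points on the circle, in [0, period)
    k : basis dimension + 1 knot count on the circle; the basis has k-1
        columns (values of the spline at the k-1 unique, evenly spaced knots)

    Returns
    -------
    X : (len(x), k-1) evaluation matrix
    S : (k-1, k-1) penalty, f' S f = integral of the squared second derivative
    """
    if k < 4:
        raise ValueError("k must be >= 4")
    x = np.asarray(x, dtype=float) % period
    knots = np.linspace(0.0, period, k)  # k-1 unique knots + wrap
    B, D = _cyclic_BD(knots)
    F = np.linalg.solve(B, D)  # m = F f
    S = D.T @ F
    S = (S + S.T) / 2.0
    K = k - 1
    h = np.diff(knots)
    j = np.clip(np.searchsorted(knots, x, side="right") - 1, 0, K - 1)
    x0 = knots[j]
    hj = h[j]
    t1 = knots[j + 1] - x  # distance to right knot
    t0 = x - x0
    a0 = t1 / hj
    a1 = t0 / hj
    c0 = (t1**3 / hj - hj * t1) / 6.0
    c1 = (t0**3 / hj - hj * t0) / 6.0
    X = np.zeros((len(x), K))
    rows = np.arange(len(x))
    X[rows, j % K] += a0
    X[rows, (j + 1) % K] += a1
    X += c0[:, None] * F[j % K, :] + c1[:, None] * F[(j + 1) % K, :]
    return X, S


def bspline_basis(
    x: np.ndarray, k: int = 10, degree: int = 3, xrange: tuple[float, float] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Cubic B-spline basis with second-derivative penalty (k columns)."""
    x = np.asarray(x, dtype=float)
    lo, hi = xrange if xrange is not None else (x.min(), x.max())
    if hi <= lo:
        hi = lo + 1.0
    n_inner = k - degree - 1
    if n_inner < 0:
        raise ValueError("k too small for cubic B-splines")
    inner = np.linspace(lo, hi, n_inner + 2)[1:-1]
    t = np.concatenate([[lo] * (degree + 1), inner, [hi] * (degree + 1)])
    X = BSpline.design_matrix(np.clip(x, lo, hi), t, degree).toarray()
    # exact Gram matrix of second derivatives via Simpson on each knot span
    grid_knots = np.unique(t)
    S = np.zeros((k, k))
    coef = np.eye(k)
    splines = [BSpline(t, coef[i], degree) for i in range(k)]
    for a, b in zip(grid_knots[:-1], grid_knots[1:]):
        pts = np.array([a, (a + b) / 2.0, b])
        w = (b - a) / 6.0 * np.array([1.0, 4.0, 1.0])
        d2 = np.array([s.derivative(2)(pts) for s in splines])
        S += (d2 * w) @ d2.T
    S = (S + S.T) / 2.0
    return X, S
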
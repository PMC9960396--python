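"""Redundancy analysis (RDA), partial RDA and two-block variance partitioning.

Quantifies how much of the (Hellinger-transformed) host community variance
is explained by phage community composition versus environmental covariates.
For response matrix Y and predictors X (both column-centred):

    r2     = trace(Yhat' Yhat) / trace(Y' Y),   Yhat = X (X'X)^- X' Y
    adj_r2 = 1 - (1 - r2) (n - 1)/(n - m - 1)   (Ezekiel adjustment)

Partial RDA residualises Y and X on a conditioning block Z first. The
two-block partition reports the unique (conditioned) adjusted fractions of
each block, their shared fraction, and the unexplained remainder; the four
fractions sum to one by construction. Significance uses Freedman-Lane
permutation of reduced-model residuals of the pseudo-F statistic with free
row permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class RdaResult:
    r2: float
    adj_r2: float
    canonical_eigenvalues: np.ndarray
    n_predictors: int
    perm_p: float | None = None


@dataclass
class VarPartResult:
    unique_x1: float
    unique_x2: float
    shared: float
    unexplained: float
    p_unique_x1: float | None
    p_unique_x2: float | None


def hellinger_transform(community: pd.DataFrame | np.ndarray):
    """sqrt of row-normalised abundances (rows = samples, columns = taxa)."""
    arr = np.asarray(community, dtype=float)
    if np.any(arr < 0):
        raise ValueError("abundances must be nonnegative")
    rowsum = arr.sum(axis=1)
    if np.any(rowsum == 0):
        bad = np.flatnonzero(rowsum == 0)
        if isinstance(community, pd.DataFrame):
            bad = list(community.index[bad])
        raise ValueError(f"all-zero sample rows: {bad}")
    out = np.sqrt(arr / rowsum[:, None])
    if isinstance(community, pd.DataFrame):
        return pd.DataFrame(out, index=community.index, columns=community.columns)
    return out


def standardize(X) -> np.ndarray:
    """Zero-mean, unit-variance columns (constant columns dropped to zero)."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _center(M: np.ndarray) -> np.ndarray:
    return M - M.mean(axis=0)


def _fit(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Least-norm projection of Y onto the column space of X."""
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return X @ beta


def _r2(Y: np.ndarray, X: np.ndarray) -> tuple[float, np.ndarray]:
    Yhat = _fit(Y, X)
    tot = float(np.sum(Y**2))
    if tot == 0:
        return 0.0, np.zeros(0)
    eig = np.linalg.svd(Yhat, compute_uv=False) ** 2 / (Y.shape[0] - 1)
    return float(np.sum(Yhat**2) / tot), eig[eig > 1e-12]


def _adjust(r2: float, n: int, m: int) -> float:
    if n - m - 1 <= 0:
        raise ValueError("need n samples > predictors + 1")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


def _rank(X: np.ndarray) -> int:
    return int(np.linalg.matrix_rank(X)) if X.size else 0


def rda(Y, X, n_perm: int = 0, seed: int = 0) -> RdaResult:
    """RDA of response matrix Y on predictor matrix X (rows = samples).

    X should be standardized beforehand (see ``standardize``). When
    ``n_perm`` > 0, a permutation test of the pseudo-F statistic (free row
    permutation of Y) provides ``perm_p``.
    """
    Y = _center(np.asarray(Y, dtype=float))
    X = _center(np.asarray(X, dtype=float))
    n = Y.shape[0]
    m = _rank(X)
    r2, eig = _r2(Y, X)
    res = RdaResult(r2, _adjust(r2, n, m), eig, m)
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        f_obs = _pseudo_f(r2, n, m)
        hits = 0
        for _ in range(n_perm):
            Yp = Y[rng.permutation(n)]
            r2p, _ = _r2(Yp, X)
            if _pseudo_f(r2p, n, m) >= f_obs - 1e-12:
                hits += 1
        res.perm_p = (hits + 1.0) / (n_perm + 1.0)
    return res


def _pseudo_f(r2: float, n: int, m: int) -> float:
    denom_df = max(n - m - 1, 1)
    return (r2 / max(m, 1)) / max((1.0 - r2) / denom_df, 1e-12)


def _residualize(M: np.ndarray, Z: np.ndarray) -> np.ndarray:
    if Z.size == 0:
        return M
    return M - _fit(M, Z)


def partial_rda(Y, X, Z, n_perm: int = 0, seed: int = 0) -> RdaResult:
    """RDA of Y on X after removing the conditioning block Z from both.

    The adjusted R2 uses the Ezekiel adjustment on the combined degrees of
    freedom, i.e. adjR2(X|Z) = adjR2(X union Z) - adjR2(Z), the
    decomposition used for variance partitioning. The permutation test uses
    Freedman-Lane: residuals of Y on Z are permuted and re-added to the
    fitted Z component.
    """
    Y = _center(np.asarray(Y, dtype=float))
    X = _center(np.asarray(X, dtype=float))
    Z = _center(np.asarray(Z, dtype=float)) if np.size(Z) else np.empty((Y.shape[0], 0))
    n = Y.shape[0]
    if Z.shape[1] == 0:
        return rda(Y, X, n_perm=n_perm, seed=seed)
    XZ = np.column_stack([X, Z])
    r2_xz, _ = _r2(Y, XZ)
    r2_z, _ = _r2(Y, Z)
    m_xz, m_z = _rank(XZ), _rank(Z)
    adj = _adjust(r2_xz, n, m_xz) - _adjust(r2_z, n, m_z)
    # conditional fit as a difference of projections: robust when X lies
    # (numerically) inside span(Z)
    Yhat_cond = _fit(Y, XZ) - _fit(Y, Z)
    tot = float(np.sum(Y**2))
    r2_cond = float(np.sum(Yhat_cond**2) / tot) if tot > 0 else 0.0
    eig = np.linalg.svd(Yhat_cond, compute_uv=False) ** 2 / (n - 1)
    eig = eig[eig > 1e-12]
    m_x = m_xz - m_z
    res = RdaResult(r2_cond, adj, eig, m_x)
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        f_obs = _partial_f(r2_xz, r2_z, n, m_xz, m_z)
        fitted_z = _fit(Y, Z)
        resid_z = Y - fitted_z
        hits = 0
        for _ in range(n_perm):
            Yp = fitted_z + resid_z[rng.permutation(n)]
            r2p_xz, _ = _r2(Yp, XZ)
            r2p_z, _ = _r2(Yp, Z)
            if _partial_f(r2p_xz, r2p_z, n, m_xz, m_z) >= f_obs - 1e-12:
                hits += 1
        res.perm_p = (hits + 1.0) / (n_perm + 1.0)
    return res


def _partial_f(r2_xz: float, r2_z: float, n: int, m_xz: int, m_z: int) -> float:
    df1 = max(m_xz - m_z, 1)
    df2 = max(n - m_xz - 1, 1)
    return ((r2_xz - r2_z) / df1) / max((1.0 - r2_xz) / df2, 1e-12)


def principal_axes(X, n_axes: int | None = None) -> np.ndarray:
    """Orthogonal principal-component axes (scores) of a standardized block."""
    Xc = _center(standardize(X))
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    keep = s > s[0] * 1e-10 if len(s) else np.zeros(0, bool)
    scores = U[:, keep] * s[keep]
    if n_axes is not None:
        scores = scores[:, :n_axes]
    return scores


def forward_select_axes(
    Y, candidate_axes: np.ndarray, alpha: float = 0.1, n_perm: int = 199, seed: int = 0
) -> list[int]:
    """Greedy forward selection of orthogonal axes with permutation stopping.

    At each step the axis adding the most explained variance is tested by
    permuting the residuals of the current model; it is kept only if its
    permutation p < alpha. Returns the selected column indices in order.
    """
    Y = _center(np.asarray(Y, dtype=float))
    axes = np.asarray(candidate_axes, dtype=float)
    n = Y.shape[0]
    rng = np.random.default_rng(seed)
    selected: list[int] = []
    remaining = list(range(axes.shape[1]))
    if alpha <= 0:
        return selected
    while remaining:
        Zcur = axes[:, selected] if selected else np.empty((n, 0))
        gains = []
        for j in remaining:
            Xj = np.column_stack([Zcur, axes[:, [j]]])
            r2, _ = _r2(Y, Xj)
            gains.append((r2, j))
        r2_best, j_best = max(gains)
        # permutation test of the added axis, permuting current-model residuals
        r2_cur, _ = _r2(Y, Zcur) if selected else (0.0, None)
        m_cur = len(selected)
        f_obs = _partial_f(r2_best, r2_cur, n, m_cur + 1, m_cur)
        fitted = _fit(Y, Zcur) if selected else np.zeros_like(Y)
        resid = Y - fitted
        hits = 0
        for _ in range(n_perm):
            Yp = fitted + resid[rng.permutation(n)]
            r2p_b, _ = _r2(Yp, np.column_stack([Zcur, axes[:, [j_best]]]))
            r2p_c, _ = _r2(Yp, Zcur) if selected else (0.0, None)
            if _partial_f(r2p_b, r2p_c, n, m_cur + 1, m_cur) >= f_obs - 1e-12:
                hits += 1
        p = (hits + 1.0) / (n_perm + 1.0)
        if p < alpha:
            selected.append(j_best)
            remaining.remove(j_best)
        else:
            break
    return selected


def variance_partition(Y, X1, X2, n_perm: int = 200, seed: int = 0) -> VarPartResult:
    """Two-block variance partition of Y between predictor blocks X1 and X2.

    unique_x1 = adjR2(X1|X2), unique_x2 = adjR2(X2|X1),
    shared = adjR2(X1 union X2) - unique_x1 - unique_x2,
    unexplained = 1 - adjR2(X1 union X2). Fractions are reported as computed
    (small negatives are not clipped) and sum to 1.
    """
    Y = _center(np.asarray(Y, dtype=float))
    X1 = _center(np.asarray(X1, dtype=float))
    X2 = _center(np.asarray(X2, dtype=float))
    n = Y.shape[0]
    both = np.column_stack([X1, X2])
    r2_both, _ = _r2(Y, both)
    adj_both = _adjust(r2_both, n, _rank(both))
    p1 = partial_rda(Y, X1, X2, n_perm=n_perm, seed=seed)
    p2 = partial_rda(Y, X2, X1, n_perm=n_perm, seed=seed + 1)
    unique1, unique2 = p1.adj_r2, p2.adj_r2
    shared = adj_both - unique1 - unique2
    return VarPartResult(
        unique_x1=unique1,
        unique_x2=unique2,
        shared=shared,
        unexplained=1.0 - adj_both,
        p_unique_x1=p1.perm_p,
        p_unique_x2=p2.perm_p,
    )
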
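"""Per-species seasonality testing and dynamic-class assignment.

Each species' abundance series is fit with a penalized additive model

    y(t) = intercept + f_cyclic(month of year) + g_smooth(elapsed months)

where ``f_cyclic`` is a cyclic cubic regression spline on the 12-month
circle and ``g_smooth`` a cubic B-spline capturing interannual trend.
Seasonality is assessed by the exact F-test between the nested unpenalized
regression-spline fits (full vs. trend-only), which is correctly calibrated
under a Gaussian null; the reported seasonal curve and its peak month come
from the penalized fit whose smoothing parameters are chosen by generalized
cross-validation (GCV). This detects non-sinusoidal seasonal shapes as well
as seasonality with interannual variation.

Species are then assigned one of four dynamic classes:

    persistent -- detected in more than 85% of samples (regardless of the
                  seasonal test);
    seasonal   -- otherwise, seasonal-spline p < 0.05;
    sporadic   -- otherwise, detected in fewer than 15% of samples;
    occasional -- everything else.

Raw p-values drive classification; Storey q-values (with a
Benjamini-Hochberg fallback) are reported alongside, with p = 1 entries
excluded from FDR estimation and assigned q = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import abundance as ab
from .splines import bspline_basis, cyclic_spline_basis
from .synthetic import SpeciesCountTable

DYNAMIC_CLASSES = ("seasonal", "persistent", "occasional", "sporadic")

_DEFAULT_LAMBDAS = tuple(np.logspace(-3.0, 5.0, 7))


def _colspace(X: np.ndarray) -> tuple[np.ndarray, int]:
    """Orthonormal basis of the column space (rank-revealing SVD)."""
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    r = int(np.sum(s > s[0] * 1e-10)) if len(s) else 0
    return U[:, :r], r


@dataclass
class SeasonalFit:
    seasonal_p: float
    trend_p: float
    seasonal_q: float  # filled in by batch FDR adjustment; nan until then
    fitted_seasonal_curve: np.ndarray  # evaluated at months 1..12
    peak_month: int
    edf_seasonal: float
    flagged: bool = False


@dataclass(frozen=True)
class ClassThresholds:
    seasonal_alpha: float = 0.05
    persistent_min: float = 0.85  # strict >
    sporadic_max: float = 0.15  # strict <


class SeasonalModelFitter:
    """Penalized additive seasonal + trend model for one sampling axis.

    Basis matrices, penalties and per-smoothing-parameter factorizations are
    precomputed once per date axis, so fitting many species sharing the same
    samples costs one small linear solve per smoothing-parameter candidate.
    """

    def __init__(
        self,
        dates: pd.PeriodIndex,
        k_seasonal: int = 8,
        k_trend: int = 10,
        lambdas=_DEFAULT_LAMBDAS,
    ):
        if k_seasonal < 4:
            raise ValueError("k_seasonal must be >= 4")
        self.dates = dates
        self.n = len(dates)
        moy = np.array([d.month for d in dates], dtype=float) - 1.0  # [0, 12)
        elapsed = np.array(
            [(d.year - dates[0].year) * 12 + (d.month - dates[0].month) for d in dates],
            dtype=float,
        )
        Xs, Ss = cyclic_spline_basis(moy, k=k_seasonal)
        Xt, St = bspline_basis(elapsed, k=k_trend)
        self._s_means = Xs.mean(axis=0)
        self._t_means = Xt.mean(axis=0)
        Xs = Xs - self._s_means  # sum-to-zero constraints for identifiability
        Xt = Xt - self._t_means
        self.ks = Xs.shape[1]
        self.kt = Xt.shape[1]
        self.X = np.column_stack([np.ones(self.n), Xs, Xt])
        p = self.X.shape[1]
        self.Ps = np.zeros((p, p))
        self.Ps[1 : 1 + self.ks, 1 : 1 + self.ks] = Ss
        self.Pt = np.zeros((p, p))
        self.Pt[1 + self.ks :, 1 + self.ks :] = St
        self.Xr = np.column_stack([np.ones(self.n), Xt])
        self.Ptr = np.zeros((self.kt + 1, self.kt + 1))
        self.Ptr[1:, 1:] = St
        self.lambdas = np.asarray(lambdas, dtype=float)
        # small ridge keeps the penalized normal equations well conditioned
        self._ridge = 1e-8
        self._grid_full = self._precompute(
            self.X, [(ls, lt) for ls in self.lambdas for lt in self.lambdas], full=True
        )
        self._k_seasonal = k_seasonal
        # orthonormal column-space bases of the nested (unpenalized) designs;
        # the seasonal F-test compares these exactly
        self._Qf, self._rank_f = _colspace(self.X)
        self._Qr, self._rank_r = _colspace(self.Xr)
        self._Q0, self._rank_0 = _colspace(np.ones((self.n, 1)))

    def _precompute(self, X, lam_pairs, full: bool = True):
        XtX = X.T @ X
        p = X.shape[1]
        grid = []
        for ls, lt in lam_pairs:
            A = XtX + ls * self.Ps + lt * self.Pt + self._ridge * np.eye(p)
            Ainv = np.linalg.inv(A)
            edf = float(np.trace(Ainv @ XtX))
            grid.append((ls, lt, Ainv, edf))
        return grid

    def _gcv_fit(self, y, X, grid):
        """Return (beta, edf, rss) at the GCV-optimal smoothing parameters."""
        Xty = X.T @ y
        yty = float(y @ y)
        best = None
        for ls, lt, Ainv, edf in grid:
            beta = Ainv @ Xty
            rss = yty - 2 * beta @ Xty + beta @ (X.T @ (X @ beta))
            rss = max(rss, 0.0)
            denom = max(self.n - edf, 1e-6)
            gcv = self.n * rss / denom**2
            if best is None or gcv < best[0]:
                best = (gcv, beta, edf, rss)
        return best[1], best[2], best[3]

    def _rss(self, y: np.ndarray, Q: np.ndarray) -> float:
        proj = Q.T @ y
        return float(max(y @ y - proj @ proj, 0.0))

    def fit(self, y) -> SeasonalFit:
        y = np.asarray(y, dtype=float)
        if len(y) != self.n:
            raise ValueError("series length must match the date axis")
        if np.all(y == 0):
            warnings.warn("all-zero series: seasonal p set to 1")
            return SeasonalFit(1.0, 1.0, np.nan, np.zeros(12), 1, 0.0, flagged=True)
        # inference: exact F-tests between nested regression-spline fits
        rss_f = self._rss(y, self._Qf)
        rss_r = self._rss(y, self._Qr)
        rss_0 = self._rss(y, self._Q0)
        df1 = self._rank_f - self._rank_r
        df2 = self.n - self._rank_f
        if rss_f <= 0 or df2 <= 0:
            seasonal_p = 1.0
        else:
            F = ((rss_r - rss_f) / df1) / (rss_f / df2)
            seasonal_p = float(stats.f.sf(F, df1, df2))
        df1t = self._rank_r - self._rank_0
        df2t = self.n - self._rank_r
        if rss_r <= 0 or df2t <= 0:
            trend_p = 1.0
        else:
            Ft = ((rss_0 - rss_r) / df1t) / (rss_r / df2t)
            trend_p = float(stats.f.sf(Ft, df1t, df2t))
        # the smoothed (GCV-penalized) fit supplies the seasonal curve
        beta_f, edf_f, _ = self._gcv_fit(y, self.X, self._grid_full)
        # fitted seasonal component on a fine month grid -> peak month
        grid = np.linspace(0.0, 12.0, 1200, endpoint=False)
        Xg, _ = cyclic_spline_basis(grid, k=self._k_seasonal)
        curve = (Xg - self._s_means) @ beta_f[1 : 1 + self.ks]
        peak = (int(np.round(grid[int(np.argmax(curve))])) % 12) + 1
        months = np.arange(12, dtype=float)
        Xm, _ = cyclic_spline_basis(months, k=self._k_seasonal)
        curve12 = (Xm - self._s_means) @ beta_f[1 : 1 + self.ks]
        return SeasonalFit(seasonal_p, trend_p, np.nan, curve12, peak, float(edf_f))


def fit_seasonal_model(
    series, dates: pd.PeriodIndex, k_seasonal: int = 8, k_trend: int = 10
) -> SeasonalFit:
    """Fit the seasonal + trend model to a single abundance series."""
    return SeasonalModelFitter(dates, k_seasonal, k_trend).fit(series)


def fdr_adjust(pvalues, pi0_method: str = "auto") -> np.ndarray:
    """Storey q-values with a Benjamini-Hochberg fallback.

    Entries with p = 1 are excluded from FDR estimation and assigned q = 1.
    pi0 is estimated as mean(p > 0.5)/0.5; when that estimate is unstable
    (fewer than 20 usable p-values, or pi0 <= 0) the BH special case pi0 = 1
    is used. Output is monotone in p and capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    q = np.ones_like(p)
    use = p < 1.0
    pu = p[use]
    m = pu.size
    if m == 0:
        return q
    if pi0_method == "bh" or m < 20:
        pi0 = 1.0
    else:
        pi0 = float(np.mean(pu > 0.5) / 0.5)
        if pi0 <= 0 or not np.isfinite(pi0):
            pi0 = 1.0
        pi0 = min(pi0, 1.0)
    order = np.argsort(pu, kind="stable")
    ranked = pu[order]
    qv = pi0 * m * ranked / np.arange(1, m + 1)
    qv = np.minimum.accumulate(qv[::-1])[::-1]
    qv = np.minimum(qv, 1.0)
    out = np.empty(m)
    out[order] = qv
    q[use] = out
    return q


def classify(
    seasonal_p: float,
    detection_fraction: float,
    thresholds: ClassThresholds = ClassThresholds(),
    precedence: str = "persistent_first",
) -> str:
    """Assign one of the four dynamic classes from p-value and detection."""
    if not (0 <= detection_fraction <= 1):
        raise ValueError("detection_fraction must be in [0, 1]")
    seasonal = seasonal_p < thresholds.seasonal_alpha
    persistent = detection_fraction > thresholds.persistent_min
    if precedence == "persistent_first":
        if persistent:
            return "persistent"
        if seasonal:
            return "seasonal"
    elif precedence == "seasonal_first":
        if seasonal:
            return "seasonal"
        if persistent:
            return "persistent"
    else:
        raise ValueError(f"unknown precedence {precedence!r}")
    if detection_fraction < thresholds.sporadic_max:
        return "sporadic"
    return "occasional"


def classify_table(
    table: SpeciesCountTable,
    dates: pd.PeriodIndex,
    thresholds: ClassThresholds = ClassThresholds(),
    precedence: str = "persistent_first",
    k_seasonal: int = 8,
    k_trend: int = 10,
    retained_only: bool = True,
) -> pd.DataFrame:
    """Seasonality test + classification for every (retained) species.

    Returns a DataFrame indexed by species with columns: fraction, class,
    seasonal_p, seasonal_q, trend_p, detection_fraction, peak_month.
    """
    at = ab.abundance_table(table, retained_only=retained_only)
    det = ab.detection_fraction(at.rpkm)
    fitter = SeasonalModelFitter(dates, k_seasonal, k_trend)
    fits = {sp: fitter.fit(at.rpkm.loc[sp].to_numpy()) for sp in at.rpkm.index}
    ps = np.array([fits[sp].seasonal_p for sp in at.rpkm.index])
    qs = fdr_adjust(ps)
    rows = []
    for i, sp in enumerate(at.rpkm.index):
        f = fits[sp]
        rows.append(
            {
                "species": sp,
                "fraction": table.fraction_label,
                "class": classify(f.seasonal_p, det.loc[sp], thresholds, precedence),
                "seasonal_p": f.seasonal_p,
                "seasonal_q": qs[i],
                "trend_p": f.trend_p,
                "detection_fraction": det.loc[sp],
                "peak_month": f.peak_month,
            }
        )
    return pd.DataFrame(rows).set_index("species")


def compare_class_composition(classes_a: dict, classes_b: dict) -> tuple[float, float, int]:
    """Pearson chi-squared comparison of two class-count compositions.

    Categories with a zero margin across both compositions are dropped (with
    a warning) and the degrees of freedom adjusted accordingly.
    """
    cats = sorted(set(classes_a) | set(classes_b))
    a = np.array([classes_a.get(c, 0) for c in cats], dtype=float)
    b = np.array([classes_b.get(c, 0) for c in cats], dtype=float)
    keep = (a + b) > 0
    if not keep.all():
        dropped = [c for c, k in zip(cats, keep) if not k]
        warnings.warn(f"dropping zero-margin categories: {dropped}")
        a, b = a[keep], b[keep]
    if len(a) < 2:
        raise ValueError("need at least two non-empty categories")
    obs = np.vstack([a, b])
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    exp = row @ col / obs.sum()
    stat = float(((obs - exp) ** 2 / exp).sum())
    df = len(a) - 1
    return stat, float(stats.chi2.sf(stat, df)), df


def class_counts(classification: pd.DataFrame) -> dict:
    return classification["class"].value_counts().to_dict()


def downsampling_robustness(
    table: SpeciesCountTable,
    dates: pd.PeriodIndex,
    factor: float = 5.0,
    **kwargs,
) -> dict:
    """Reclassify after downsampling read counts and compare compositions.

    Counts are divided by ``factor`` (values below 1 zeroed), RPKM recomputed
    against the correspondingly reduced library sizes, the seasonal model
    refit, and the two class compositions compared by chi-squared.
    """
    original = classify_table(table, dates, **kwargs)
    down_table = ab.downsample_table(table, factor)
    downsampled = classify_table(down_table, dates, **kwargs)
    ca, cb = class_counts(original), class_counts(downsampled)
    stat, p, df = compare_class_composition(ca, cb)
    return {
        "original": original,
        "downsampled": downsampled,
        "chi2": stat,
        "p_value": p,
        "df": df,
    }
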
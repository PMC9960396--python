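"""Whole-community statistics: richness, rarefaction, rank abundance and
Bray-Curtis time-decay seasonality.

Richness uses the bias-corrected incidence-based Chao estimator

    chao = S_obs + ((N-1)/N) * q1*(q1-1) / (2*(q2+1))

where q1 and q2 are the numbers of species seen in exactly one and exactly
two samples, with the matching variance estimator

    var = A*q1*(q1-1)/(2*(q2+1))
        + A^2*q1*(2*q1-1)^2/(4*(q2+1)^2)
        + A^2*q1^2*q2*(q1-1)^2/(4*(q2+1)^4),   A = (N-1)/N,

(the bias-corrected incidence analogue of Chao 1987). Community seasonality
is quantified by binning pairwise Bray-Curtis *similarities* (1 -
dissimilarity) by the number of calendar months separating samples and
fitting an annual harmonic (fixed 12-month period) over lags 3-36 months by
ordinary least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.spatial.distance import braycurtis as _braycurtis
import statsmodels.api as sm


@dataclass
class RichnessEstimate:
    s_obs: int
    chao: float
    chao_se: float  # nan when undefined (single sample)
    n_samples: int
    q1: int
    q2: int


@dataclass
class LagSimilarity:
    lag_months: int
    similarities: list[float]
    mean: float
    se: float


@dataclass
class SineFit:
    intercept: float
    amp_sin: float
    amp_cos: float
    period_months: float
    p_value: float
    r2: float


def chao_incidence(incidence: pd.DataFrame | np.ndarray) -> RichnessEstimate:
    """Bias-corrected incidence-based Chao richness from a species x sample
    boolean (or 0/1) matrix. Species never observed are ignored."""
    inc = np.asarray(incidence, dtype=bool)
    if inc.ndim != 2:
        raise ValueError("incidence must be 2-D (species x sample)")
    n_samples = inc.shape[1]
    freq = inc.sum(axis=1)
    freq = freq[freq > 0]
    s_obs = int(len(freq))
    q1 = int(np.sum(freq == 1))
    q2 = int(np.sum(freq == 2))
    if n_samples < 1:
        raise ValueError("need at least one sample")
    a = (n_samples - 1) / n_samples
    chao = s_obs + a * q1 * (q1 - 1) / (2.0 * (q2 + 1))
    if n_samples < 2:
        warnings.warn("single sample: Chao SE undefined")
        se = float("nan")
    else:
        var = (
            a * q1 * (q1 - 1) / (2.0 * (q2 + 1))
            + a**2 * q1 * (2 * q1 - 1) ** 2 / (4.0 * (q2 + 1) ** 2)
            + a**2 * q1**2 * q2 * (q1 - 1) ** 2 / (4.0 * (q2 + 1) ** 4)
        )
        se = float(np.sqrt(var))
    return RichnessEstimate(s_obs, float(chao), se, n_samples, q1, q2)


def rarefaction_curve(counts, depths) -> np.ndarray:
    """Expected richness at each subsample depth m (hypergeometric expectation).

    E[S(m)] = sum_i [1 - C(n - n_i, m) / C(n, m)], computed in log space.
    """
    counts = np.asarray(counts, dtype=np.int64)
    counts = counts[counts > 0]
    n = int(counts.sum())
    depths = np.atleast_1d(np.asarray(depths, dtype=np.int64))
    if np.any(depths > n) or np.any(depths < 0):
        raise ValueError("depths must be in [0, total reads]")
    out = np.empty(len(depths), dtype=float)
    for k, m in enumerate(depths):
        # log C(n - n_i, m) - log C(n, m); term is 0 when n - n_i < m
        ok = (n - counts) >= m
        lg = (
            gammaln(n - counts[ok] + 1)
            - gammaln(m + 1)
            - gammaln(n - counts[ok] - m + 1)
            - (gammaln(n + 1) - gammaln(m + 1) - gammaln(n - m + 1))
        )
        out[k] = len(counts) - np.exp(lg).sum()
    return out


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y); nan when both all-zero."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("abundances must be nonnegative")
    if x.sum() == 0 and y.sum() == 0:
        warnings.warn("Bray-Curtis undefined for two all-zero vectors")
        return float("nan")
    return float(_braycurtis(x, y))


def _month_lag(a: pd.Period, b: pd.Period) -> int:
    return abs((a.year - b.year) * 12 + (a.month - b.month))


def similarity_vs_lag(
    abund: pd.DataFrame, dates: pd.PeriodIndex
) -> dict[int, LagSimilarity]:
    """Pairwise Bray-Curtis similarity (1 - dissimilarity) binned by month lag.

    ``abund`` is species x sample with columns aligned to ``dates``.  The SE
    of each bin is the sample standard deviation / sqrt(number of pairs).
    """
    if abund.shape[1] != len(dates):
        raise ValueError("dates must align with abundance columns")
    cols = abund.to_numpy().T
    bins: dict[int, list[float]] = {}
    for i in range(len(dates)):
        for j in range(i + 1, len(dates)):
            lag = _month_lag(dates[i], dates[j])
            sim = 1.0 - bray_curtis(cols[i], cols[j])
            bins.setdefault(lag, []).append(sim)
    out = {}
    for lag in sorted(bins):
        vals = np.asarray(bins[lag])
        se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan")
        out[lag] = LagSimilarity(lag, list(vals), float(vals.mean()), se)
    return out


def fit_lag_sine(
    lagged: dict[int, LagSimilarity],
    lag_range: tuple[int, int] = (3, 36),
    period_months: float = 12.0,
    per_pair: bool = False,
) -> SineFit:
    """OLS fit of similarity on an annual harmonic over the given lag range.

    y ~ 1 + sin(2*pi*lag/12) + cos(2*pi*lag/12); the p-value is the F-test of
    both harmonic coefficients jointly zero. By default the per-lag *mean*
    similarities are fit (one point per lag bin); ``per_pair=True`` fits all
    pairwise values instead.
    """
    lags, ys = [], []
    for lag, ls in sorted(lagged.items()):
        if not (lag_range[0] <= lag <= lag_range[1]):
            continue
        if per_pair:
            lags.extend([lag] * len(ls.similarities))
            ys.extend(ls.similarities)
        else:
            lags.append(lag)
            ys.append(ls.mean)
    if len(set(lags)) < 4:
        raise ValueError("need >=4 distinct lags in range for the harmonic fit")
    lags_arr = np.asarray(lags, dtype=float)
    y = np.asarray(ys, dtype=float)
    X = np.column_stack(
        [
            np.sin(2 * np.pi * lags_arr / period_months),
            np.cos(2 * np.pi * lags_arr / period_months),
        ]
    )
    model = sm.OLS(y, sm.add_constant(X)).fit()
    return SineFit(
        intercept=float(model.params[0]),
        amp_sin=float(model.params[1]),
        amp_cos=float(model.params[2]),
        period_months=period_months,
        p_value=float(model.f_pvalue),
        r2=float(model.rsquared),
    )


def rank_abundance(abund: pd.DataFrame) -> pd.DataFrame:
    """Species ranked by descending mean RPKM across samples (ties by id)."""
    if abund.shape[0] == 0:
        raise ValueError("empty abundance table")
    mean = abund.mean(axis=1)
    df = mean.rename("mean_abundance").to_frame()
    # stable sort after sorting the index implements "ties broken by id"
    df = df.sort_index().sort_values("mean_abundance", ascending=False, kind="stable")
    df["rank"] = np.arange(1, len(df) + 1)
    return df
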
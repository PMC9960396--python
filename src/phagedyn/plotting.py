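"""Plotting hooks for the whole-community statistics."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .community import LagSimilarity, SineFit  # noqa: E402


def plot_rank_abundance(rank_df, path: str) -> None:
    """Rank-abundance curve (log y) from a `rank_abundance` table."""
    fig, axis = plt.subplots(figsize=(5, 4))
    axis.semilogy(rank_df["rank"], rank_df["mean_abundance"].clip(lower=1e-12), lw=1.2)
    axis.set_xlabel("species rank")
    axis.set_ylabel("mean abundance (RPKM)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_lag_similarity(
    lagged: dict[int, LagSimilarity], fit: SineFit | None, path: str
) -> None:
    """Mean similarity vs. month lag with standard-error bars and sine fit."""
    lags = sorted(lagged)
    means = [lagged[l].mean for l in lags]
    ses = [lagged[l].se for l in lags]
    fig, axis = plt.subplots(figsize=(6, 4))
    axis.errorbar(lags, means, yerr=ses, fmt="ko", ms=3, capsize=2)
    if fit is not None:
        grid = np.linspace(min(lags), max(lags), 300)
        curve = (
            fit.intercept
            + fit.amp_sin * np.sin(2 * np.pi * grid / fit.period_months)
            + fit.amp_cos * np.cos(2 * np.pi * grid / fit.period_months)
        )
        axis.plot(grid, curve, "k-", lw=1)
    axis.set_xlabel("months between samples")
    axis.set_ylabel("community similarity (1 - Bray-Curtis)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
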
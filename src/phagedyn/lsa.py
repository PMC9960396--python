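"""Delay-aware local similarity analysis (LSA) networks.

For two rank-normalised monthly series, the local similarity score is the
largest absolute partial sum of the pointwise product over any contiguous
aligned segment, allowing the two series to be shifted against each other by
up to ``max_delay`` months, scaled by the series length. The dynamic
programme is a Kadane maximum-subarray scan along each alignment diagonal:

    P[i,j] = max(0, P[i-1,j-1] + x_i * y_j)   (positive associations)
    N[i,j] = max(0, N[i-1,j-1] - x_i * y_j)   (negative associations)

restricted to |i - j| <= max_delay; missing observations contribute 0 to a
run (they neither extend nor reset it). Significance comes either from
seeded permutations of one series or from a theoretical tail approximation:
under the null the running segment sum behaves like a Brownian motion, so
``sqrt(n) * ls_score`` is compared to the distribution of the maximum
absolute value of a standard Brownian motion on [0, 1], raised to the power
(2*max_delay + 1) to account for the near-independent delay offsets.

Networks keep only edges that pass simultaneous p-value, FDR (Q) and
Spearman-correlation filters, and connected components smaller than a
minimum node count are pruned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .dynamics import fdr_adjust


@dataclass(frozen=True)
class LSAFilters:
    p_max: float = 0.0015
    q_max: float = 0.05
    rho_min: float = 0.6
    absolute_rho: bool = True  # False keeps positive correlations only


@dataclass
class LSAEdge:
    node_a: str
    node_b: str
    role_a: str
    role_b: str
    ls_score: float
    optimal_delay: int
    p_value: float
    q_value: float
    spearman_rho: float
    sign: str


@dataclass
class LSANetwork:
    graph: nx.Graph
    edges: pd.DataFrame
    tally: dict[str, int]
    n_pruned_nodes: int


class ConstantSeriesError(ValueError):
    """Raised when a series has no variation and cannot be rank-normalised."""


def normalize_series(x) -> np.ndarray:
    """Rank-normal transform of a series with missing values (NaN).

    Observed values are replaced by standard-normal quantiles of their ranks
    (mid-ranks for ties), then centred and scaled to unit variance. Missing
    points remain NaN.
    """
    x = np.asarray(x, dtype=float)
    obs = ~np.isnan(x)
    vals = x[obs]
    if len(vals) < 4:
        raise ValueError("need >=4 non-missing points")
    if np.all(vals == vals[0]):
        raise ConstantSeriesError("constant series cannot be rank-normalised")
    ranks = stats.rankdata(vals)
    z = stats.norm.ppf(ranks / (len(vals) + 1.0))
    z = (z - z.mean()) / z.std()
    out = np.full_like(x, np.nan)
    out[obs] = z
    return out


def local_similarity(x, y, max_delay: int = 3) -> tuple[float, int, str]:
    """Local similarity score, optimal delay and sign of two normalised series.

    Returns ``(ls_score, delay, sign)`` where ``delay`` is the shift of ``y``
    relative to ``x`` (``y`` lags ``x`` by ``delay`` months when positive)
    and sign is '+' or '-'. Ties prefer smaller |delay|, then positive sign.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must share the month axis")
    n = len(x)
    if n < 4:
        raise ValueError("series too short")
    best = (0.0, 0, "+")
    delays = sorted(range(-max_delay, max_delay + 1), key=lambda d: (abs(d), d < 0))
    for d in delays:
        # diagonal j - i = d: products x_i * y_{i+d}
        if d >= 0:
            prod = x[: n - d] * y[d:]
        else:
            prod = x[-d:] * y[: n + d]
        prod = np.where(np.isnan(prod), 0.0, prod)
        pos = neg = 0.0
        best_pos = best_neg = 0.0
        for v in prod:
            pos = max(0.0, pos + v)
            neg = max(0.0, neg - v)
            best_pos = max(best_pos, pos)
            best_neg = max(best_neg, neg)
        for score, sign in ((best_pos / n, "+"), (best_neg / n, "-")):
            if score > best[0] + 1e-15:
                best = (score, d, sign)
    return best


def lsa_pvalue(
    x,
    y,
    max_delay: int = 3,
    method: str = "permutation",
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    ls_score: float | None = None,
) -> float:
    """p-value for the local similarity of two normalised series.

    permutation -- proportion of >=-extreme scores over seeded permutations
    of ``y``'s observed values (add-one correction).
    theoretical -- tail of max|Brownian motion| applied to sqrt(n)*ls_score,
    with the (2D+1)-power delay correction (approximation to analytic LSA
    significance).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("n must be >= 4")
    if ls_score is None:
        ls_score = local_similarity(x, y, max_delay)[0]
    if method == "theoretical":
        return theoretical_pvalue(ls_score, n, max_delay)
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse permutation p-value")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    obs_idx = np.flatnonzero(~np.isnan(y))
    vals = y[obs_idx]
    hits = 0
    yp = y.copy()
    for _ in range(n_perm):
        yp[obs_idx] = vals[rng.permutation(len(vals))]
        if local_similarity(x, yp, max_delay)[0] >= ls_score - 1e-12:
            hits += 1
    return (hits + 1.0) / (n_perm + 1.0)


def _max_abs_brownian_cdf(x: float, terms: int = 100) -> float:
    """P(max_{0<=t<=1} |W(t)| <= x) for standard Brownian motion W."""
    if x <= 0:
        return 0.0
    s = 0.0
    for k in range(terms):
        s += ((-1) ** k / (2 * k + 1)) * np.exp(-((2 * k + 1) ** 2) * np.pi**2 / (8 * x**2))
    return min(max(4.0 / np.pi * s, 0.0), 1.0)


def theoretical_pvalue(ls_score: float, n: int, max_delay: int = 3) -> float:
    """Brownian-motion tail approximation to the LSA null distribution."""
    xstat = ls_score * np.sqrt(n)
    cdf = _max_abs_brownian_cdf(xstat)
    return float(1.0 - cdf ** (2 * max_delay + 1))


def spearman_on_overlap(x, y) -> float:
    """Spearman rho on the delay-0 overlap of non-missing months."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 4:
        return float("nan")
    rho, _ = stats.spearmanr(x[ok], y[ok])
    return float(rho)


def _edge_category(role_a: str, role_b: str) -> str:
    ra, rb = sorted([role_a, role_b])
    return f"{ra}--{rb}"


def build_network(
    series: dict[str, tuple[str, np.ndarray]],
    max_delay: int = 3,
    filters: LSAFilters = LSAFilters(),
    min_subnetwork: int = 5,
    p_method: str = "theoretical",
    n_perm: int = 1000,
    seed: int = 0,
    node_attrs: dict[str, dict] | None = None,
) -> LSANetwork:
    """All-pairs LSA network across phage, host and environment series.

    ``series`` maps node id -> (role, raw series on the common month axis,
    NaN for missing). Series are rank-normalised here; constant series are
    excluded with a warning. Edges must satisfy p < p_max, Q < q_max and
    |rho| >= rho_min (or rho >= rho_min when ``absolute_rho`` is False);
    connected components with fewer than ``min_subnetwork`` nodes are pruned.
    The theoretical p-value method is the default because the all-pairs edge
    count makes per-edge permutation impractical; pass
    ``p_method='permutation'`` for seeded permutation tests.
    """
    rng = np.random.default_rng(seed)
    normalised: dict[str, tuple[str, np.ndarray]] = {}
    for node, (role, raw) in series.items():
        try:
            normalised[node] = (role, normalize_series(raw))
        except (ConstantSeriesError, ValueError) as e:
            warnings.warn(f"excluding node {node!r}: {e}")
    nodes = sorted(normalised)
    rows = []
    for a, b in combinations(nodes, 2):
        role_a, xa = normalised[a]
        role_b, xb = normalised[b]
        ls, delay, sign = local_similarity(xa, xb, max_delay)
        if p_method == "permutation":
            p = lsa_pvalue(xa, xb, max_delay, "permutation", n_perm, rng, ls_score=ls)
        else:
            p = theoretical_pvalue(ls, len(xa), max_delay)
        rho = spearman_on_overlap(xa, xb)
        rows.append(
            {
                "node_a": a,
                "node_b": b,
                "role_a": role_a,
                "role_b": role_b,
                "ls_score": ls,
                "optimal_delay": delay,
                "sign": sign,
                "p_value": p,
                "spearman_rho": rho,
            }
        )
    edges = pd.DataFrame(rows)
    if len(edges):
        edges["q_value"] = fdr_adjust(edges["p_value"].to_numpy())
        rho_ok = (
            edges["spearman_rho"].abs() >= filters.rho_min
            if filters.absolute_rho
            else edges["spearman_rho"] >= filters.rho_min
        )
        keep = (
            (edges["p_value"] < filters.p_max)
            & (edges["q_value"] < filters.q_max)
            & rho_ok.fillna(False)
        )
        kept = edges[keep].reset_index(drop=True)
    else:
        edges["q_value"] = []
        kept = edges

    g = nx.Graph()
    for node in nodes:
        role = normalised[node][0]
        attrs = (node_attrs or {}).get(node, {})
        g.add_node(node, role=role, **attrs)
    for _, r in kept.iterrows():
        g.add_edge(
            r.node_a,
            r.node_b,
            ls_score=float(r.ls_score),
            optimal_delay=int(r.optimal_delay),
            sign=r.sign,
            p_value=float(r.p_value),
            q_value=float(r.q_value),
            spearman_rho=float(r.spearman_rho),
        )
    # prune small subnetworks; isolated nodes count as components of size 1
    pruned = 0
    for comp in list(nx.connected_components(g)):
        if len(comp) < min_subnetwork:
            g.remove_nodes_from(comp)
            pruned += len(comp)
    final_edges = kept[
        kept.apply(lambda r: g.has_edge(r.node_a, r.node_b), axis=1)
    ].reset_index(drop=True) if len(kept) else kept
    tally: dict[str, int] = {}
    for _, r in final_edges.iterrows():
        cat = _edge_category(r.role_a, r.role_b)
        tally[cat] = tally.get(cat, 0) + 1
    return LSANetwork(graph=g, edges=final_edges, tally=tally, n_pruned_nodes=pruned)


def write_graphml(network: LSANetwork, path: str) -> None:
    nx.write_graphml(network.graph, path)
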
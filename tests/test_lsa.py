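"""Rank-normalisation, the delay-restricted local similarity DP against a
brute-force oracle, significance methods and network filtering."""

import numpy as np
import pytest

from phagedyn.lsa import (
    ConstantSeriesError,
    LSAFilters,
    build_network,
    local_similarity,
    lsa_pvalue,
    normalize_series,
    theoretical_pvalue,
)


def brute_force_ls(x, y, max_delay):
    """Exhaustive search over all contiguous matched segments and delays."""
    n = len(x)
    best = (0.0, 0, "+")
    for d in sorted(range(-max_delay, max_delay + 1), key=lambda d: (abs(d), d < 0)):
        prod = x[: n - d] * y[d:] if d >= 0 else x[-d:] * y[: n + d]
        prod = np.where(np.isnan(prod), 0.0, prod)
        for i in range(len(prod)):
            for j in range(i, len(prod)):
                s = prod[i : j + 1].sum()
                for score, sign in ((s / n, "+"), (-s / n, "-")):
                    if score > best[0] + 1e-15:
                        best = (score, d, sign)
    return best


class TestNormalize:
    def test_mean_zero_unit_variance(self, rng):
        z = normalize_series(rng.normal(size=40))
        assert abs(z.mean()) < 1e-9
        assert abs(z.std() - 1.0) < 1e-9

    def test_monotone_series_stays_monotone(self):
        z = normalize_series(np.arange(10, dtype=float))
        assert np.all(np.diff(z) > 0)

    def test_missing_mask_preserved(self, rng):
        x = rng.normal(size=48)
        x[[3, 17, 40]] = np.nan
        z = normalize_series(x)
        assert np.isnan(z[[3, 17, 40]]).all()
        assert np.sum(~np.isnan(z)) == 45

    def test_constant_series_flagged(self):
        with pytest.raises(ConstantSeriesError):
            normalize_series(np.full(10, 2.0))


class TestLocalSimilarity:
    def test_self_similarity_maximal_positive_at_zero_delay(self, rng):
        x = normalize_series(rng.normal(size=30))
        ls, delay, sign = local_similarity(x, x, 3)
        assert delay == 0 and sign == "+"
        # every term of the diagonal is positive, so the whole series matches
        assert ls == pytest.approx(np.sum(x * x) / len(x))

    def test_antisymmetry_of_negated_series(self, rng):
        x = normalize_series(rng.normal(size=30))
        ls_pos, _, _ = local_similarity(x, x, 3)
        ls_neg, _, sign = local_similarity(x, -x, 3)
        assert ls_neg == pytest.approx(ls_pos)
        assert sign == "-"

    def test_swap_negates_delay(self, rng):
        for _ in range(50):
            x = rng.normal(size=20)
            y = rng.normal(size=20)
            s1, d1, g1 = local_similarity(x, y, 3)
            s2, d2, g2 = local_similarity(y, x, 3)
            assert s1 == pytest.approx(s2)
            assert d1 == -d2 and g1 == g2

    def test_matches_brute_force_on_short_series(self, rng):
        for t in range(200):
            n = int(rng.integers(4, 11))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            if t % 3 == 0:
                x[int(rng.integers(0, n))] = np.nan
            got = local_similarity(x, y, 3)
            want = brute_force_ls(x, y, 3)
            assert got[0] == pytest.approx(want[0])
            assert got[1:] == want[1:]

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            local_similarity(np.ones(3), np.ones(3), 3)


class TestPvalues:
    def test_identical_series_hit_minimal_permutation_p(self, rng):
        x = normalize_series(rng.normal(size=48))
        p = lsa_pvalue(x, x, 3, "permutation", n_perm=200, seed=1)
        assert p == pytest.approx(1.0 / 201.0)

    def test_permutation_null_uniform(self, rng):
        from scipy.stats import kstest

        ps = []
        for _ in range(300):
            x = normalize_series(rng.normal(size=48))
            y = normalize_series(rng.normal(size=48))
            ps.append(lsa_pvalue(x, y, 3, "permutation", n_perm=200, seed=rng))
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_theoretical_tracks_permutation_in_the_tail(self, rng):
        ratios = []
        for _ in range(150):
            x = normalize_series(rng.normal(size=48))
            y = normalize_series(rng.normal(size=48))
            ls = local_similarity(x, y, 3)[0]
            pp = lsa_pvalue(x, y, 3, "permutation", n_perm=500, seed=rng, ls_score=ls)
            if 0.001 <= pp <= 0.1:
                ratios.append(theoretical_pvalue(ls, 48, 3) / pp)
        ratios = np.asarray(ratios)
        assert len(ratios) >= 5
        assert np.mean((ratios > 0.5) & (ratios < 2.0)) >= 0.8
        assert np.all((ratios > 0.25) & (ratios < 4.0))

    def test_small_n_perm_warns(self, rng):
        x = normalize_series(rng.normal(size=20))
        with pytest.warns(UserWarning):
            lsa_pvalue(x, x, 3, "permutation", n_perm=50, seed=0)


class TestNetwork:
    @staticmethod
    def _planted(rng, n_noise=10, n_months=48):
        t = np.arange(n_months)
        signal = np.exp(np.cos(2 * np.pi * (t - 6) / 12) * 2)
        series = {
            "phage": ("virus_viral_fraction", signal * np.exp(rng.normal(0, 0.2, n_months))),
            "host": ("host_asv", signal * np.exp(rng.normal(0, 0.2, n_months))),
        }
        for i in range(n_noise):
            series[f"noise{i:02d}"] = (
                "virus_viral_fraction",
                np.exp(rng.normal(0, 1, n_months)),
            )
        return series

    def test_planted_coupling_recovered_and_tallied(self, rng):
        net = build_network(self._planted(rng), min_subnetwork=2, seed=0)
        assert net.graph.has_edge("phage", "host")
        assert net.tally.get("host_asv--virus_viral_fraction", 0) >= 1

    def test_filter_monotone_in_thresholds(self, rng):
        series = self._planted(rng, n_noise=6)
        loose = build_network(
            series, filters=LSAFilters(p_max=0.2, q_max=0.5, rho_min=0.0),
            min_subnetwork=1, seed=0,
        )
        tight = build_network(
            series, filters=LSAFilters(p_max=0.001, q_max=0.05, rho_min=0.6),
            min_subnetwork=1, seed=0,
        )
        loose_edges = {tuple(sorted(e)) for e in loose.graph.edges}
        tight_edges = {tuple(sorted(e)) for e in tight.graph.edges}
        assert tight_edges <= loose_edges

    def test_low_rho_edge_excluded_despite_tiny_p(self, rng):
        series = self._planted(rng)
        net = build_network(
            series, filters=LSAFilters(rho_min=0.999), min_subnetwork=1, seed=0
        )
        assert net.graph.number_of_edges() == 0

    def test_small_components_pruned(self, rng):
        # only the planted pair passes the filters -> a 2-node component,
        # removed when the minimum subnetwork size is 5
        series = self._planted(rng)
        net = build_network(series, min_subnetwork=5, seed=0)
        assert not net.graph.has_node("phage")
        assert len(net.edges) == 0

    def test_constant_series_excluded_with_warning(self, rng):
        series = self._planted(rng, n_noise=3)
        series["flat"] = ("environment", np.full(48, 1.0))
        with pytest.warns(UserWarning):
            net = build_network(series, min_subnetwork=1, seed=0)
        assert not net.graph.has_node("flat")
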
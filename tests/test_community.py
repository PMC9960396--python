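"""Richness estimation, rarefaction, Bray-Curtis time decay and the annual
harmonic fit of community similarity."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phagedyn.community import (
    bray_curtis,
    chao_incidence,
    fit_lag_sine,
    rank_abundance,
    rarefaction_curve,
    similarity_vs_lag,
)


def _incidence(freqs, n_samples):
    """Species x sample 0/1 matrix where species i occurs in freqs[i] samples."""
    m = np.zeros((len(freqs), n_samples), dtype=bool)
    for i, f in enumerate(freqs):
        m[i, :f] = True
    return m


class TestChao:
    def test_no_uniques_means_no_unseen_mass(self):
        inc = _incidence([3] * 7 + [2] * 3, 5)
        est = chao_incidence(inc)
        assert est.s_obs == 10 and est.q1 == 0 and est.q2 == 3
        assert est.chao == pytest.approx(10.0)

    def test_hand_computed_example(self):
        # chao = 10 + (9/10) * 4*3 / (2*3) = 11.8
        inc = _incidence([1] * 4 + [2] * 2 + [3] * 4, 10)
        est = chao_incidence(inc)
        assert (est.q1, est.q2) == (4, 2)
        assert est.chao == pytest.approx(11.8)
        # variance terms: 0.9*2 + 0.81*4*49/36 + 0.81*32*9/(4*81) = 6.93
        assert est.chao_se == pytest.approx(np.sqrt(1.8 + 4.41 + 0.72), rel=1e-12)

    def test_complete_incidence_equals_observed(self):
        inc = _incidence([3, 4, 5, 3], 6)
        assert chao_incidence(inc).chao == pytest.approx(4.0)

    @pytest.mark.parametrize(
        "freqs,n,expected",
        [
            # chao = S + ((N-1)/N) * q1(q1-1)/(2(q2+1)); arithmetic done by hand
            ([1, 1, 2, 3], 4, 4 + 0.75 * 2 / 4),  # q1=2,q2=1 -> 4.375
            ([1] * 5, 3, 5 + (2 / 3) * 20 / 2),  # q1=5,q2=0 -> 11.666...
            ([2] * 6, 8, 6.0),  # q1=0 -> S_obs
            ([1, 2, 2, 2, 3, 3], 5, 6.0),  # q1=1 -> zero numerator
            ([1, 1, 1, 2, 4], 6, 5 + (5 / 6) * 6 / 4),  # q1=3,q2=1 -> 6.25
        ],
    )
    def test_hand_calculations_on_constructed_matrices(self, freqs, n, expected):
        assert chao_incidence(_incidence(freqs, n)).chao == pytest.approx(expected)

    def test_single_sample_flags_se_undefined(self):
        with pytest.warns(UserWarning):
            est = chao_incidence(_incidence([1, 1], 1))
        assert np.isnan(est.chao_se)


class TestRarefaction:
    def test_full_depth_returns_observed_richness(self):
        counts = np.array([5, 3, 2])
        assert rarefaction_curve(counts, [10])[0] == pytest.approx(3.0)

    def test_depth_one_returns_one(self):
        assert rarefaction_curve([5, 3, 2], [1])[0] == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        # oracle: mean richness over all C(10, 4) labeled subsamples
        counts = [5, 3, 2]
        reads = [s for s, c in enumerate(counts) for _ in range(c)]
        richness = [
            len(set(combo)) for combo in itertools.combinations(reads, 4)
        ]
        expected = np.mean(richness)
        assert rarefaction_curve(counts, [4])[0] == pytest.approx(expected, rel=1e-12)

    def test_depth_beyond_total_rejected(self):
        with pytest.raises(ValueError):
            rarefaction_curve([2, 2], [5])


class TestBrayCurtis:
    def test_identical_vectors_are_zero(self):
        assert bray_curtis([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(0.0)

    def test_disjoint_support_is_one(self):
        assert bray_curtis([1.0, 0.0], [0.0, 2.0]) == pytest.approx(1.0)

    def test_hand_arithmetic_example(self):
        assert bray_curtis([1.0, 2.0], [3.0, 0.0]) == pytest.approx(4.0 / 6.0)

    def test_double_zero_flagged(self):
        with pytest.warns(UserWarning):
            assert np.isnan(bray_curtis([0.0, 0.0], [0.0, 0.0]))

    @settings(max_examples=50, deadline=None)
    @given(c=st.floats(0.01, 100))
    def test_scaling_closed_form(self, c):
        x = np.array([1.0, 2.5, 0.5, 4.0])
        assert bray_curtis(x, c * x) == pytest.approx(abs(1 - c) / (1 + c), rel=1e-9)


class TestSimilarityVsLag:
    def test_identical_samples_one_year_apart(self):
        abund = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, 2.0]})
        dates = pd.PeriodIndex(["2010-01", "2011-01"], freq="M")
        lagged = similarity_vs_lag(abund, dates)
        assert lagged[12].mean == pytest.approx(1.0)

    def test_three_monthly_samples_enumerate_pairs(self):
        abund = pd.DataFrame(np.random.default_rng(0).random((4, 3)))
        dates = pd.PeriodIndex(["2010-01", "2010-02", "2010-03"], freq="M")
        lagged = similarity_vs_lag(abund, dates)
        assert sorted(lagged) == [1, 2]
        assert len(lagged[1].similarities) == 2 and len(lagged[2].similarities) == 1

    def test_sample_order_invariance(self, rng):
        abund = pd.DataFrame(rng.random((5, 4)))
        dates = pd.PeriodIndex(["2010-01", "2010-04", "2010-02", "2011-01"], freq="M")
        perm = [3, 1, 0, 2]
        lagged_a = similarity_vs_lag(abund, dates)
        lagged_b = similarity_vs_lag(abund.iloc[:, perm], dates[perm])
        assert sorted(lagged_a) == sorted(lagged_b)
        for lag in lagged_a:
            assert sorted(lagged_a[lag].similarities) == pytest.approx(
                sorted(lagged_b[lag].similarities)
            )


class TestLagSine:
    @staticmethod
    def _bins(lags, values):
        from phagedyn.community import LagSimilarity

        return {
            l: LagSimilarity(l, [v], v, float("nan")) for l, v in zip(lags, values)
        }

    def test_noiseless_cosine_recovered_exactly(self):
        lags = np.arange(3, 37)
        y = 0.5 + 0.2 * np.cos(2 * np.pi * lags / 12)
        fit = fit_lag_sine(self._bins(lags, y))
        assert fit.amp_cos == pytest.approx(0.2, abs=1e-10)
        assert fit.amp_sin == pytest.approx(0.0, abs=1e-10)
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_series_not_significant(self):
        lags = np.arange(3, 37)
        fit = fit_lag_sine(self._bins(lags, np.full(len(lags), 0.4)))
        assert abs(fit.amp_cos) < 1e-10 and abs(fit.amp_sin) < 1e-10
        assert fit.p_value > 0.99 or np.isnan(fit.p_value)

    def test_null_rejection_rate_near_alpha(self, rng):
        lags = np.arange(3, 37)
        rejections = 0
        n_rep = 500
        for _ in range(n_rep):
            fit = fit_lag_sine(self._bins(lags, rng.normal(size=len(lags))))
            rejections += fit.p_value < 0.05
        rate = rejections / n_rep
        assert 0.02 <= rate <= 0.09

    def test_too_few_lags_rejected(self):
        with pytest.raises(ValueError):
            fit_lag_sine(self._bins([3, 4, 5], [0.1, 0.2, 0.3]))


class TestRankAbundance:
    def test_single_species(self):
        out = rank_abundance(pd.DataFrame([[1.0, 2.0]], index=["only"]))
        assert list(out["rank"]) == [1]

    def test_permutation_invariant(self, rng):
        abund = pd.DataFrame(rng.random((10, 5)), index=[f"s{i}" for i in range(10)])
        a = rank_abundance(abund)
        b = rank_abundance(abund.sample(frac=1.0, random_state=3))
        pd.testing.assert_frame_equal(a, b)

    def test_monotone_nonincreasing_on_lognormal_community(self, rng):
        abund = pd.DataFrame(rng.lognormal(0, 1.5, size=(100, 8)))
        out = rank_abundance(abund)
        assert (np.diff(out["mean_abundance"]) <= 1e-12).all()
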
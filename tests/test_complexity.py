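"""Entropy and self-similarity: oracle equivalence and known-exponent recovery."""

import warnings

import numpy as np
import pytest
from scipy import stats as scs

from hrvdcan.complexity import (EntropyConfig, PRESETS, alpha_bands,
                                coarse_grain, dfa_alpha, mdfa_profile,
                                mse_bands, mse_profile, sampen)
from hrvdcan.series import MultiscaleProfile, UndefinedResultWarning
from hrvdcan.synthetic import power_law_noise

from conftest import make_nn


def sampen_bruteforce(x, m, r):
    """Independent O(n^2) oracle: direct definition, plain pair loops."""
    x = np.asarray(x, dtype=float)
    n = x.size
    nt = n - m
    a = b = 0
    for i in range(nt):
        for j in range(i + 1, nt):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    if a == 0 or b == 0:
        return float("nan")
    return -np.log(a / b)


class TestSampEn:
    def test_equals_bruteforce_oracle_on_random_series(self):
        rng = np.random.default_rng(7)
        for _ in range(15):
            n = int(rng.integers(60, 300))
            x = rng.standard_normal(n)
            for m in (1, 2):
                r = 0.2 * x.std(ddof=1)
                expected = sampen_bruteforce(x, m, r)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", UndefinedResultWarning)
                    got = sampen(x, m=m, r_abs=r)
                if np.isnan(expected):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(expected, abs=1e-12)

    def test_iid_gaussian_matches_analytic_match_probability(self):
        # for iid data SampEn -> -ln P(|X-Y| <= r) with X-Y ~ N(0, 2)
        rng = np.random.default_rng(11)
        x = rng.standard_normal(5000)
        expected = -np.log(2 * scs.norm.cdf(0.15 / np.sqrt(2)) - 1)
        assert sampen(x, m=1, r_abs=0.15) == pytest.approx(expected, abs=0.1)

    def test_periodic_series_has_near_zero_entropy(self):
        # each value uniquely determines its successor: perfect predictability
        x = np.tile([1.0, 2.0, 3.0, 4.0], 100)
        assert sampen(x, m=1, r_abs=0.1) == pytest.approx(0.0, abs=0.02)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            sampen(np.ones(20), r_abs=0.1)

    def test_no_matches_signalled_as_undefined(self):
        x = np.arange(100, dtype=float)  # monotone ramp, tiny tolerance
        with pytest.warns(UndefinedResultWarning):
            assert np.isnan(sampen(x, m=1, r_abs=1e-6))


class TestCoarseGrain:
    def test_scale_one_is_identity(self):
        x = np.arange(10.0)
        np.testing.assert_array_equal(coarse_grain(x, 1), x)

    def test_nonoverlapping_matches_block_means(self):
        x = np.arange(12.0)
        got = coarse_grain(x, 3, "nonoverlapping")
        np.testing.assert_allclose(got, [1.0, 4.0, 7.0, 10.0])

    def test_overlapping_is_moving_average(self):
        x = np.array([1.0, 2.0, 4.0, 8.0])
        np.testing.assert_allclose(coarse_grain(x, 2, "overlapping"),
                                   [1.5, 3.0, 6.0])


class TestMSEProfile:
    def test_scale_one_equals_raw_sampen(self, white_noise_nn):
        prof = mse_profile(white_noise_nn)
        raw = sampen(white_noise_nn.intervals, m=1,
                     r_abs=0.15 * white_noise_nn.intervals.std(ddof=1))
        assert prof.values[0] == pytest.approx(raw, abs=1e-12)

    def test_white_noise_decreases_with_scale_under_fixed_tolerance(
            self, white_noise_nn):
        prof = mse_profile(white_noise_nn)
        # averaging shrinks variance while r stays fixed: matches get easier
        assert (np.diff(prof.values) < 0.05).all()
        assert prof.values[-1] < prof.values[0]

    def test_tau_mapping_uses_mean_nn(self):
        nn = make_nn(np.full(600, 1000.0) + np.random.default_rng(0)
                     .standard_normal(600))
        prof = mse_profile(nn)
        np.testing.assert_allclose(prof.tau, prof.beat_scales
                                   * nn.intervals.mean() / 1000, rtol=1e-9)

    def test_replication_variant_differs_from_default(self, white_noise_nn):
        default = mse_profile(white_noise_nn)
        costa = mse_profile(white_noise_nn, PRESETS["costa-replication"],
                            max_tau_s=5.0)
        s = 3  # compare at beat scale 3
        d_val = default.values[np.flatnonzero(default.beat_scales == s)[0]]
        c_val = costa.values[np.flatnonzero(costa.beat_scales == s)[0]]
        assert d_val != pytest.approx(c_val, abs=1e-6)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            mse_profile(make_nn(np.full(100, 900.0)))


class TestMSEBands:
    def test_constant_profile(self):
        prof = MultiscaleProfile(np.arange(1, 25, 0.9), np.full(27, 1.5))
        hf, lf = mse_bands(prof)
        assert hf == 1.5 and lf == 1.5

    def test_hand_average(self):
        prof = MultiscaleProfile(np.array([2.5, 5.0, 10.0]),
                                 np.array([1.0, 2.0, 3.0]))
        hf, lf = mse_bands(prof)
        assert hf == pytest.approx(1.5)
        assert lf == pytest.approx(3.0)

    def test_band_membership_follows_tau_not_beat_count(self):
        # at 700 ms mean NN, beat scales 4..9 give tau in [2.8, 6.3] s: HF band
        tau = np.arange(1, 36) * 0.7
        prof = MultiscaleProfile(tau, np.ones(35), np.arange(1, 36))
        in_hf = (tau >= 2.5) & (tau < 6.7)
        assert set(prof.beat_scales[in_hf]) == set(range(4, 10))

    def test_empty_band_flagged(self):
        prof = MultiscaleProfile(np.array([1.0, 2.0]), np.array([1.0, 1.0]))
        with pytest.warns(UndefinedResultWarning):
            hf, lf = mse_bands(prof)
        assert np.isnan(hf) and np.isnan(lf)


class TestDFA:
    def test_white_noise_exponent_half(self):
        vals = [dfa_alpha(np.random.default_rng(s).standard_normal(4096))
                for s in range(10)]
        assert np.mean(vals) == pytest.approx(0.5, abs=0.05)

    def test_integrated_white_noise_exponent_three_halves(self):
        vals = [dfa_alpha(np.cumsum(np.random.default_rng(s)
                                    .standard_normal(4096)))
                for s in range(10)]
        assert np.mean(vals) == pytest.approx(1.5, abs=0.1)

    def test_fgn_exponent_recovery(self):
        # 1/f^beta noise has DFA exponent (beta + 1) / 2
        for beta, truth in ((0.6, 0.8), (-0.6, 0.2)):
            vals = [dfa_alpha(power_law_noise(4096, beta,
                                              np.random.default_rng(100 + s)))
                    for s in range(10)]
            assert np.mean(vals) == pytest.approx(truth, abs=0.1)

    def test_profile_sinusoid_short_scales_smooth_limit(self):
        # tau far below the period: locally smooth signal, alpha near 2
        n = 2048
        x = 900 + 100 * np.sin(2 * np.pi * np.arange(n) / 512)
        nn = make_nn(x)
        prof = mdfa_profile(nn, min_box=4, max_box=32)
        assert prof.values[:4].mean() > 1.6

    def test_profile_white_noise_flat_at_half(self, white_noise_nn):
        prof = mdfa_profile(white_noise_nn, min_box=10)
        assert np.nanmean(prof.values) == pytest.approx(0.5, abs=0.15)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            mdfa_profile(make_nn(np.full(300, 900.0)))


class TestAlphaBands:
    def test_constant_profile(self):
        prof = MultiscaleProfile(np.arange(3, 70, 2.0), np.full(34, 0.9))
        short, long_ = alpha_bands(prof)
        assert short == pytest.approx(0.9)
        assert long_ == pytest.approx(0.9)

    def test_band_edges_follow_stated_ranges(self):
        tau = np.array([4.0, 5.0, 11.0, 17.0, 18.0, 60.0, 61.0])
        vals = np.array([10.0, 1.0, 2.0, 100.0, 3.0, 5.0, 200.0])
        prof = MultiscaleProfile(tau, vals)
        short, long_ = alpha_bands(prof)
        assert short == pytest.approx(1.5)   # 5 and 11 inclusive
        assert long_ == pytest.approx(4.0)   # 17 and 61 exclusive

    def test_missing_coverage_flagged(self):
        prof = MultiscaleProfile(np.array([1.0, 2.0]), np.array([0.5, 0.5]))
        with pytest.warns(UndefinedResultWarning):
            short, long_ = alpha_bands(prof)
        assert np.isnan(short) and np.isnan(long_)
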
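"""Feature bank vs independent brute-force / closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import stats

from emgresp.features import (
    DegenerateSegmentError,
    FeatureConfig,
    amplitude_features,
    ar_and_cepstrum,
    cardinality,
    difference_features,
    emg_histogram,
    extract_feature_vector,
    feature_names,
    spectral_features,
    threshold_counts,
)
from emgresp.preprocessing import SteadySegment


def _seg(x, fs=2000.0):
    return SteadySegment(samples=np.asarray(x, float), start_index=0, fs=fs)


EPS0 = FeatureConfig(deadzone_eps=0.0)


class TestHandComputedVector:
    """x = [1, -2, 3, -4]: every time-domain feature checked by arithmetic."""

    x = np.array([1.0, -2.0, 3.0, -4.0])

    def test_amplitude_features(self):
        f = amplitude_features(_seg(self.x))
        assert f["p2p"] == 7.0
        assert f["MAV"] == 2.5
        assert f["RMS"] == pytest.approx(np.sqrt(30 / 4))
        assert f["VAR"] == pytest.approx(29 / 3)
        assert f["logD"] == pytest.approx(np.exp(np.mean(np.log([1, 2, 3, 4]))))

    def test_difference_features(self):
        f = difference_features(_seg(self.x))
        assert f["wLen"] == 15.0
        assert f["M2"] == 83.0
        assert f["DAMV"] == 5.0
        assert f["DVARV"] == 41.5

    def test_threshold_counts_at_zero_eps(self):
        f = threshold_counts(_seg(self.x), EPS0)
        assert (f["ZERC"], f["SSC"], f["wAmp"]) == (3, 2, 3)


class TestAmplitudeProperties:
    def test_zero_signal(self):
        f = amplitude_features(_seg(np.zeros(16)))
        assert f["p2p"] == 0.0 and f["MAV"] == 0.0 and f["RMS"] == 0.0
        assert f["logD"] == pytest.approx(1e-12)

    def test_homogeneity_under_scaling(self, rng):
        x = rng.standard_normal(256)
        f1, f2 = amplitude_features(_seg(x)), amplitude_features(_seg(2 * x))
        assert f2["MAV"] == pytest.approx(2 * f1["MAV"])
        assert f2["RMS"] == pytest.approx(2 * f1["RMS"])
        assert f2["p2p"] == pytest.approx(2 * f1["p2p"])
        assert f2["VAR"] == pytest.approx(4 * f1["VAR"])

    def test_mav_rms_p2p_ordering(self, rng):
        x = rng.standard_normal(512)
        x -= x.mean()
        f = amplitude_features(_seg(x))
        assert f["MAV"] <= f["RMS"] <= f["p2p"]


class TestDifferenceProperties:
    def test_constant_signal_all_zero(self):
        f = difference_features(_seg(np.full(32, 2.0)))
        assert set(f.values()) == {0.0}

    def test_m2_dvarv_identity(self, rng):
        x = rng.standard_normal(100)
        f = difference_features(_seg(x))
        assert f["M2"] == pytest.approx((x.size - 2) * f["DVARV"])
        assert f["M2"] == pytest.approx(np.sum(np.diff(x) ** 2))

    def test_sinusoid_m2_closed_form(self):
        fs, freq, n = 2000.0, 90.0, 200_000
        x = np.sin(2 * np.pi * freq * np.arange(n) / fs)
        f = difference_features(_seg(x, fs))
        assert f["M2"] / n == pytest.approx(2 * np.sin(np.pi * freq / fs) ** 2, rel=1e-3)


class TestThresholdCounts:
    def test_enumeration_oracle_random_signal(self, rng):
        x = rng.standard_normal(200)
        eps = 0.5
        f = threshold_counts(_seg(x), FeatureConfig(deadzone_eps=eps))
        zerc = sum(
            1
            for i in range(199)
            if x[i] * x[i + 1] < 0 and abs(x[i] - x[i + 1]) >= eps
        )
        ssc = sum(
            1
            for i in range(1, 199)
            if (x[i] - x[i - 1]) * (x[i] - x[i + 1]) >= eps
        )
        wamp = sum(1 for i in range(199) if abs(x[i + 1] - x[i]) >= eps)
        assert (f["ZERC"], f["SSC"], f["wAmp"]) == (zerc, ssc, wamp)

    def test_monotone_ramp_has_no_crossings_or_slope_changes(self):
        f = threshold_counts(_seg(np.linspace(0.1, 1.0, 50)), EPS0)
        assert f["ZERC"] == 0 and f["SSC"] == 0

    def test_dominating_threshold_zeroes_all_counts(self, rng):
        """ZERC/wAmp thresholds compare first differences (<= p2p); SSC
        compares a product of two slopes (<= p2p^2), so a threshold above
        p2p^2 + p2p dominates every count."""
        x = rng.standard_normal(100)
        p2p = np.ptp(x)
        f = threshold_counts(_seg(x), FeatureConfig(deadzone_eps=p2p**2 + p2p + 1))
        assert (f["ZERC"], f["SSC"], f["wAmp"]) == (0, 0, 0)

    def test_counts_non_increasing_in_eps(self, rng):
        x = rng.standard_normal(300)
        prev = None
        for eps in (0.0, 0.1, 0.5, 1.0, 2.0):
            f = threshold_counts(_seg(x), FeatureConfig(deadzone_eps=eps))
            if prev is not None:
                assert f["ZERC"] <= prev["ZERC"]
                assert f["SSC"] <= prev["SSC"]
                assert f["wAmp"] <= prev["wAmp"]
            prev = f


class TestSpectralFeatures:
    def test_pure_tone_centres_both_statistics(self):
        fs = 2000.0
        x = np.sin(2 * np.pi * 120.0 * np.arange(8192) / fs)
        f = spectral_features(_seg(x, fs))
        bin_hz = fs / 1024
        assert abs(f["MeanF"] - 120.0) <= bin_hz
        assert abs(f["MedF"] - 120.0) <= bin_hz

    def test_two_equal_tones_mean_at_midpoint(self):
        fs = 2000.0
        t = np.arange(16384) / fs
        x = np.sin(2 * np.pi * 100 * t) + np.sin(2 * np.pi * 200 * t)
        f = spectral_features(_seg(x, fs))
        assert abs(f["MeanF"] - 150.0) <= fs / 1024

    def test_bandpassed_noise_median_matches_periodogram_oracle(self, rng):
        from scipy import signal as sps

        fs = 2000.0
        sos = sps.butter(4, [20, 450], btype="bandpass", fs=fs, output="sos")
        x = sps.sosfiltfilt(sos, rng.standard_normal(2**16))
        f = spectral_features(_seg(x, fs))
        freq, p = sps.periodogram(x, fs=fs)
        cum = np.cumsum(p)
        med_oracle = freq[np.searchsorted(cum, cum[-1] / 2)]
        assert abs(f["MedF"] - med_oracle) < 10.0


class TestArAndCepstrum:
    def test_ar1_parameter_recovery(self, rng):
        n = 60_000
        x = np.zeros(n)
        e = rng.standard_normal(n)
        for i in range(1, n):
            x[i] = 0.9 * x[i - 1] + e[i]
        f = ar_and_cepstrum(_seg(x))
        assert f["ARCO1"] == pytest.approx(0.9, abs=0.02)
        for k in (2, 3, 4):
            assert abs(f[f"ARCO{k}"]) < 0.05

    def test_white_noise_coefficients_near_zero(self, rng):
        f = ar_and_cepstrum(_seg(rng.standard_normal(60_000)))
        for k in (1, 2, 3, 4):
            assert abs(f[f"ARCO{k}"]) < 0.05

    def test_cepstrum_matches_log_spectrum_inverse_transform(self, rng):
        """Recursion output equals the cepstrum of the fitted AR model's
        log power spectrum obtained by inverse FFT (independent path)."""
        from scipy import signal as sps

        sos = sps.butter(2, [50, 300], btype="bandpass", fs=2000.0, output="sos")
        x = sps.sosfiltfilt(sos, rng.standard_normal(8192))
        f = ar_and_cepstrum(_seg(x))
        rho = np.array([f[f"ARCO{k}"] for k in (1, 2, 3, 4)])
        nfft = 2**16
        w = 2 * np.pi * np.arange(nfft) / nfft
        A = 1 - sum(rho[k] * np.exp(-1j * w * (k + 1)) for k in range(4))
        ceps_oracle = np.fft.ifft(-2 * np.log(np.abs(A))).real[1:5]
        for k in (1, 2, 3, 4):
            assert f[f"Ceps{k}"] == pytest.approx(ceps_oracle[k - 1], abs=1e-6)

    def test_zero_variance_segment_rejected(self):
        with pytest.raises(DegenerateSegmentError):
            ar_and_cepstrum(_seg(np.full(1000, 1.0)))


class TestHistogram:
    def test_gaussian_bin_masses_match_normal_cdf(self, rng):
        n = 200_000
        x = rng.standard_normal(n)
        h = emg_histogram(_seg(x))
        sd = np.std(x)
        edges = np.linspace(-3 * sd, 3 * sd, 10)
        probs = np.diff(stats.norm.cdf(edges, scale=1.0))
        for got, p in zip(h, probs):
            se = np.sqrt(p * (1 - p) / n)
            assert abs(got - p) < 3 * se + 1e-4

    def test_constant_signal_all_mass_in_centre(self):
        h = emg_histogram(_seg(np.full(100, 0.5)))
        assert h[4] == 1.0 and h.sum() == 1.0

    def test_negated_signal_reverses_histogram(self, rng):
        x = rng.standard_normal(1000) + 0.2 * rng.standard_normal(1000) ** 2
        np.testing.assert_allclose(
            emg_histogram(_seg(x)), emg_histogram(_seg(-x))[::-1]
        )


class TestCardinality:
    def test_constant_signal_has_one_value(self):
        assert cardinality(_seg(np.full(50, 1.23))) == 1

    def test_tolerance_clusters_nearby_values(self):
        assert cardinality(_seg([0.0, 0.5, 1.0]), FeatureConfig(card_tol=0.6)) == 2

    def test_distinct_samples_counted_exactly(self):
        x = np.arange(40, dtype=float)
        assert cardinality(_seg(x), FeatureConfig(card_tol=0.5)) == 40


class TestFullVector:
    def test_vector_composes_individual_operations(self, rng):
        x = rng.standard_normal(2048)
        cfg = FeatureConfig()
        fv = extract_feature_vector(_seg(x), cfg)
        assert set(fv) == set(feature_names(cfg))
        assert fv["MAV"] == amplitude_features(_seg(x), cfg)["MAV"]
        assert fv["M2"] == difference_features(_seg(x), cfg)["M2"]
        assert fv["SSC"] == threshold_counts(_seg(x), cfg)["SSC"]
        assert fv["MedF"] == spectral_features(_seg(x), cfg)["MedF"]
        assert fv["Card"] == cardinality(_seg(x), cfg)

    def test_shape_features_scale_invariant(self, rng):
        x = rng.standard_normal(2048)
        cfg = FeatureConfig(deadzone_eps=0.0)
        f1 = extract_feature_vector(_seg(x), cfg)
        f2 = extract_feature_vector(_seg(2 * x), cfg)
        for name in ("ZERC", "SSC", "MedF", "MeanF", "ARCO1", "ARCO2", "Ceps1"):
            assert f2[name] == pytest.approx(f1[name], rel=1e-9)
        for name in ("MAV", "RMS", "p2p"):
            assert f2[name] == pytest.approx(2 * f1[name])

    def test_all_features_finite(self, rng):
        fv = extract_feature_vector(_seg(rng.standard_normal(2048) * 0.01))
        assert all(np.isfinite(v) for v in fv.values())


_signals = hnp.arrays(
    np.float64,
    st.integers(min_value=8, max_value=64),
    elements=st.floats(-5.0, 5.0, allow_nan=False, width=64),
)


class TestGenerativeInvariants:
    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(_signals)
    def test_difference_identities_hold_everywhere(self, x):
        f = difference_features(_seg(x))
        assert f["M2"] == pytest.approx(np.sum(np.diff(x) ** 2))
        assert f["M2"] == pytest.approx((x.size - 2) * f["DVARV"])
        assert f["DAMV"] == pytest.approx(f["wLen"] / (x.size - 1))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(_signals)
    def test_amplitude_ordering_on_centred_signals(self, x):
        x = x - x.mean()
        f = amplitude_features(_seg(x))
        assert f["MAV"] <= f["RMS"] + 1e-12
        assert f["RMS"] <= f["p2p"] + 1e-12

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(_signals, st.floats(0.0, 3.0))
    def test_counts_bounded_and_thresholded(self, x, eps):
        f = threshold_counts(_seg(x), FeatureConfig(deadzone_eps=eps))
        f0 = threshold_counts(_seg(x), FeatureConfig(deadzone_eps=0.0))
        assert 0 <= f["ZERC"] <= f0["ZERC"]
        assert 0 <= f["wAmp"] <= f0["wAmp"]
        assert 0 <= f["SSC"] <= x.size - 2
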
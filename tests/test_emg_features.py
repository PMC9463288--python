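import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from endoeval.emg_features import (
    FeatureError,
    Spectrum,
    amplitude_features,
    channel_features,
    imu_features,
    morphology_features,
    power_spectrum,
    spectral_features,
)
from .oracles import amplitude_oracle, auc_oracle, morphology_oracle, spectral_oracle


class TestPowerSpectrum:
    def test_sinusoid_peak_at_its_frequency(self):
        rate = 200.0
        t = np.arange(2000) / rate
        s = power_spectrum(np.sin(2 * np.pi * 40.0 * t), rate, band=(10, 95))
        assert s.frequencies[np.argmax(s.power)] == pytest.approx(40.0, abs=0.11)

    def test_white_noise_band_power_tracks_variance(self, rng):
        rate = 200.0
        x = rng.standard_normal(20000)
        s = power_spectrum(x, rate, band=(10, 95))
        df = s.frequencies[1] - s.frequencies[0]
        band_fraction = (95 - 10) / (rate / 2)
        assert np.sum(s.power) * df == pytest.approx(x.var() * band_fraction, rel=0.1)

    def test_parseval_full_band(self, rng):
        rate = 200.0
        x = rng.standard_normal(4096)
        s = power_spectrum(x, rate, band=(0, rate / 2))
        df = s.frequencies[1] - s.frequencies[0]
        assert np.sum(s.power) * df == pytest.approx(np.var(x), rel=1e-6)

    def test_constant_signal_all_zero_power(self):
        s = power_spectrum(np.full(256, 3.3), 200.0)
        assert np.allclose(s.power, 0.0)

    def test_too_short_signal_flagged(self):
        with pytest.raises(FeatureError):
            power_spectrum(np.zeros(10), 200.0)


class TestSpectralFeatures:
    def test_direct_argmax_argmin(self):
        s = Spectrum(np.array([20.0, 40.0, 60.0]), np.array([1.0, 5.0, 2.0]), (10, 95))
        assert spectral_features(s) == (40.0, 20.0, 20.0, 5.0, 1.0)

    def test_uniform_power_ties_to_band_edge(self):
        s = Spectrum(np.array([20.0, 40.0, 60.0]), np.ones(3), (10, 95))
        f_max, f_min, f_range, *_ = spectral_features(s)
        assert f_max == f_min == 20.0 and f_range == 0.0

    def test_signed_f_range_may_be_negative(self):
        s = Spectrum(np.array([20.0, 60.0]), np.array([0.5, 2.0]), (10, 95))
        assert spectral_features(s)[2] == 40.0
        s = Spectrum(np.array([20.0, 60.0]), np.array([2.0, 0.5]), (10, 95))
        assert spectral_features(s)[2] == -40.0

    def test_absolute_f_range_option(self, rng):
        x = rng.standard_normal(512)
        signed = channel_features(x, 200.0, signed_f_range=True)
        unsigned = channel_features(x, 200.0, signed_f_range=False)
        assert unsigned.f_Range == abs(signed.f_Range)


class TestAmplitudeFeatures:
    def test_worked_example(self):
        v_max, v_min, v_range, v_rms, v_var = amplitude_features([3.0, -1.0, 2.0])
        assert (v_max, v_min, v_range) == (3.0, -1.0, 4.0)
        assert v_rms == pytest.approx(np.sqrt(14 / 3))
        assert v_var == pytest.approx(np.var([3.0, -1.0, 2.0]))

    def test_constant_signal(self):
        v_max, v_min, v_range, v_rms, v_var = amplitude_features(np.full(10, -2.5))
        assert v_range == 0.0 and v_rms == 2.5 and v_var == 0.0

    def test_sinusoid_rms_closed_form(self):
        t = np.arange(20000) / 200.0
        x = 3.0 * np.sin(2 * np.pi * 7.0 * t)
        assert amplitude_features(x)[3] == pytest.approx(3.0 / np.sqrt(2), rel=0.01)

    def test_time_reversal_invariance(self, rng):
        x = rng.standard_normal(257)
        assert amplitude_features(x) == pytest.approx(
            amplitude_features(x[::-1]), rel=1e-12
        )


class TestMorphologyFeatures:
    def test_alternating_sequence(self):
        ssc, zc, wfl = morphology_features([1.0, -1.0, 1.0, -1.0], per_sample=False)
        assert (ssc, zc, wfl) == (2.0, 3.0, 6.0)

    def test_monotone_has_no_slope_changes(self):
        ssc, _, _ = morphology_features(np.arange(50.0), per_sample=False)
        assert ssc == 0.0

    def test_random_sign_walk_wfl(self, rng):
        steps = rng.choice([-1.0, 1.0], size=500)
        x = np.concatenate([[0.0], np.cumsum(steps)])
        _, _, wfl = morphology_features(x, per_sample=False)
        assert wfl == x.size - 1

    def test_per_sample_averaging_divides_by_n(self, rng):
        x = rng.standard_normal(100)
        raw = morphology_features(x, per_sample=False)
        avg = morphology_features(x, per_sample=True)
        assert avg == tuple(v / 100 for v in raw)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_sign_flip_invariance(self, seed):
        x = np.random.default_rng(seed).standard_normal(64)
        ssc, zc, _ = morphology_features(x, per_sample=False)
        ssc2, zc2, _ = morphology_features(-x, per_sample=False)
        assert (ssc, zc) == (ssc2, zc2)

    @given(st.floats(0.1, 100.0), st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_wfl_scales_linearly(self, c, seed):
        x = np.random.default_rng(seed).standard_normal(64)
        _, _, wfl = morphology_features(x, per_sample=False)
        _, _, wfl_scaled = morphology_features(c * x, per_sample=False)
        assert wfl_scaled == pytest.approx(c * wfl, rel=1e-9)


class TestImuFeatures:
    def test_constant_trace_auc(self):
        ones = np.ones(100)
        f = imu_features(ones, ones, ones, f_max_mean=40.0, per_sample=False)
        assert f.Roll_AUC == f.Pitch_AUC == f.Yaw_AUC == 99.0
        assert f.FES == pytest.approx(40.0 / 99.0)

    def test_fes_ratio_formula(self):
        n = 1000
        # constant traces with per-sample AUC ~ (10, 20, 30)
        mk = lambda c: np.full(n, c)
        f = imu_features(mk(10), mk(20), mk(30), f_max_mean=40.0, per_sample=True)
        # constant c integrates to c (n-1)/n per sample
        assert f.FES == pytest.approx(40.0 / (20.0 * (n - 1) / n))

    def test_abs_sine_auc_closed_form(self):
        t = np.linspace(0, 200 * np.pi, 200000)
        x = np.abs(np.sin(t))
        f = imu_features(x, x, x, f_max_mean=0.0, per_sample=True)
        assert f.Roll_AUC == pytest.approx(2 / np.pi, rel=0.01)

    def test_zero_auc_gives_missing_fes(self):
        z = np.zeros(50)
        assert np.isnan(imu_features(z, z, z, 40.0).FES)


class TestOracleEquivalence:
    """Every armband-side feature matches the brute-force reference."""

    def test_random_fixtures_match_oracles(self, rng):
        for _ in range(100):
            x = rng.standard_normal(rng.integers(64, 200)) * rng.uniform(0.5, 20)
            v = amplitude_features(x)
            assert v == pytest.approx(amplitude_oracle(list(x)), rel=1e-10)
            m = morphology_features(x, per_sample=True)
            assert m == pytest.approx(morphology_oracle(list(x), True), rel=1e-10)
            f = imu_features(x, x * 2, x - 1, 40.0, per_sample=True)
            for got, trace in ((f.Roll_AUC, x), (f.Pitch_AUC, 2 * x), (f.Yaw_AUC, x - 1)):
                assert got == pytest.approx(auc_oracle(list(trace), True), rel=1e-10)

    def test_spectral_matches_direct_dft(self, rng):
        from .oracles import periodogram_oracle

        rate = 200.0
        for _ in range(5):
            x = rng.standard_normal(128)
            s = power_spectrum(x, rate, band=(0, rate / 2))
            freqs, power = periodogram_oracle(list(x), rate)
            assert np.allclose(s.frequencies, freqs, atol=1e-9)
            assert np.allclose(s.power, power, rtol=1e-8, atol=1e-12)
            got = spectral_features(s)
            assert got == pytest.approx(spectral_oracle(list(s.frequencies), list(s.power)), rel=1e-8)


def test_channel_permutation_permutes_features(rng):
    x = rng.standard_normal((8, 400))
    feats = [channel_features(x[c], 200.0).as_dict() for c in range(8)]
    perm = rng.permutation(8)
    feats_perm = [channel_features(x[c], 200.0).as_dict() for c in perm]
    for i, p in enumerate(perm):
        assert feats_perm[i] == feats[p]
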
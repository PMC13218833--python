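"""aEEG extraction and cleaning rules against direct-arithmetic oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

from nvcoh import preprocess as pp
from nvcoh import simulate as sim


@pytest.fixture(scope="module")
def filt256():
    return pp.design_bandpass(fs=256.0)


class TestFilterDesign:
    def test_linear_phase_symmetry(self, filt256):
        assert np.allclose(filt256.coefficients, filt256.coefficients[::-1])

    def test_passband_sinusoid_preserved(self, filt256):
        fs = 256.0
        t = np.arange(int(20 * fs)) / fs
        x = np.sin(2 * np.pi * 10.0 * t)
        y = pp.apply_bandpass(x, filt256)
        core = y[int(5 * fs):-int(5 * fs)]
        assert abs(np.max(np.abs(core)) - 1.0) < 0.05

    def test_stopband_attenuation(self, filt256):
        # frequency response at 0.5 Hz down at least 20 dB from passband
        assert filt256.attenuation_db(0.5) >= 20.0
        assert filt256.attenuation_db(1.0) >= 20.0
        assert filt256.attenuation_db(20.0) >= 20.0

    def test_invalid_edges_rejected(self):
        with pytest.raises(pp.PreprocessError):
            pp.design_bandpass(fs=256.0, passband=(2.0, 15.0),
                               stopband=(3.0, 20.0))

    def test_explicit_insufficient_order_rejected(self):
        with pytest.raises(pp.PreprocessError, match="numtaps"):
            pp.design_bandpass(fs=256.0, numtaps=21)


class TestEnvelope:
    def test_constant_sinusoid_envelope(self):
        # rectified sine has mean 2A/pi; the smoothed envelope sits there
        fs, A, f0 = 256.0, 10.0, 10.0
        t = np.arange(int(30 * fs)) / fs
        env = pp.compute_aeeg(A * np.sin(2 * np.pi * f0 * t), fs)
        core = env[int(2 * fs):-int(2 * fs)]
        assert abs(core.mean() - 2 * A / np.pi) / (2 * A / np.pi) < 0.05
        assert core.std() / core.mean() < 0.10

    def test_zero_signal_zero_envelope(self):
        env = pp.compute_aeeg(np.zeros(1000), 256.0)
        assert np.all(env == 0.0)

    def test_envelope_tracks_amplitude_modulation(self):
        # after the percentile windows, the aEEG series follows the modulator
        fs = 64.0
        t = np.arange(int(2400 * fs)) / fs
        modulator = 1.0 + 0.5 * np.sin(2 * np.pi * t / 300.0)
        rng = np.random.default_rng(0)
        carrier = sim._carrier(len(t), fs, (2.0, 15.0), rng)
        env = pp.compute_aeeg(carrier * modulator, fs)
        # average away envelope-estimator noise over 30 s (far below the
        # 300-s modulation period) before correlating
        from scipy.ndimage import uniform_filter1d

        env_slow = uniform_filter1d(env, int(30 * fs), mode="nearest")
        sl = slice(int(60 * fs), -int(60 * fs))
        r = np.corrcoef(env_slow[sl], modulator[sl])[0, 1]
        assert r > 0.9


class TestPercentileDownsampler:
    def test_constant_input_gives_zero(self):
        out = pp.envelope_downsample(np.full(1000, 7.0), 100.0, 1.0)
        assert np.allclose(out.values, 0.0)

    def test_sinusoid_matches_dense_percentile_oracle(self):
        # oracle: P90-P10 of a finely sampled sinusoid over whole cycles
        A, fs, f0 = 10.0, 1000.0, 2.0
        t = np.arange(int(100 * fs)) / fs
        x = A * np.sin(2 * np.pi * f0 * t)
        dense = np.percentile(x, 90) - np.percentile(x, 10)
        assert abs(dense - 2 * A * np.sin(0.4 * np.pi)) < 0.05
        out = pp.envelope_downsample(x, fs, 0.1)   # 10-s windows, 20 cycles
        assert np.allclose(out.values, dense, atol=0.1)

    def test_output_length_is_floor_duration_times_rate(self):
        # 20 h at 256 Hz down to the 0.21 Hz oximeter rate -> 15120 samples
        n_in = int(20 * 3600 * 256)
        out = pp.envelope_downsample(np.zeros(n_in), 256.0, 0.21)
        assert len(out.values) == 15120
        assert np.allclose(np.diff(out.time_h) * 3600.0, 1 / 0.21)

    def test_window_too_short_rejected(self):
        with pytest.raises(pp.PreprocessError):
            pp.envelope_downsample(np.zeros(100), 3.0, 1.0)


class TestClipRule:
    def test_example_replacement(self):
        series = pp.AEEGSeries(values=np.array([10.0, 30.0, 12.0]), rate=1.0,
                               time_h=np.arange(3) / 3600.0)
        out = pp.clip_aeeg_artifacts(series)
        assert np.allclose(out.values, [10.0, 10.0, 12.0])
        assert out.cleaning_log[0][0] == 1

    def test_all_below_threshold_unchanged(self):
        series = pp.AEEGSeries(values=np.array([1.0, 24.9, 12.0]), rate=1.0,
                               time_h=np.arange(3) / 3600.0)
        out = pp.clip_aeeg_artifacts(series)
        assert np.array_equal(out.values, series.values)
        assert out.cleaning_log == []

    def test_leading_invalid_takes_first_valid(self):
        series = pp.AEEGSeries(values=np.array([40.0, 30.0, 12.0, 50.0]),
                               rate=1.0, time_h=np.arange(4) / 3600.0)
        out = pp.clip_aeeg_artifacts(series)
        assert np.allclose(out.values, [12.0, 12.0, 12.0, 12.0])

    def test_all_invalid_is_error(self):
        series = pp.AEEGSeries(values=np.array([30.0, 40.0]), rate=1.0,
                               time_h=np.arange(2) / 3600.0)
        with pytest.raises(pp.PreprocessError, match="no valid samples"):
            pp.clip_aeeg_artifacts(series)


class TestTrendRule:
    def test_linear_series_unchanged(self):
        t = np.arange(50) / 3600.0
        v = 3.0 + 100.0 * t
        out = pp.trend_outlier_replace(v, t, 1.0, mode="absolute_5uV")
        assert np.allclose(out.values, v)
        assert out.replaced_indices == []

    def test_aeeg_spike_replaced(self):
        t = np.arange(50) / 3600.0
        v = 3.0 + 100.0 * t
        v[20] += 10.0
        out = pp.trend_outlier_replace(v, t, 1.0, mode="absolute_5uV")
        assert 20 in out.replaced_indices
        clean = 3.0 + 100.0 * t
        assert np.allclose(np.delete(out.values, 20), np.delete(clean, 20))
        assert out.values[20] == pytest.approx(clean[19])

    def test_scto2_drop_replaced_by_relative_rule(self):
        rng = np.random.default_rng(0)
        v = 70.0 + rng.normal(0, 1.0, 60)
        v[30] = 40.0   # > 20% below the ~70% trend
        t = np.arange(60) / 0.21 / 3600.0
        out = pp.trend_outlier_replace(v, t, 0.21, mode="relative_20pct")
        assert out.replaced_indices == [30]
        assert abs(out.values[30] - v[29]) < 1e-12

    def test_degenerate_time_axis_rejected(self):
        with pytest.raises(pp.PreprocessError):
            pp.trend_outlier_replace(np.ones(5), np.zeros(5), 1.0,
                                     mode="absolute_5uV")


class TestDetrend:
    def test_exact_quadratic_removed(self):
        t = np.linspace(0, 20, 200)
        v = 1.0 + 2.0 * t - 0.3 * t ** 2
        out = pp.poly_detrend(v, t, 1.0, order=2)
        assert np.max(np.abs(out.values)) < 1e-9

    def test_sinusoid_survives_detrending(self):
        # leakage of a sinusoid into the quadratic basis decays as ~1/cycles;
        # the residual must match the exact LS-projection oracle
        t = np.linspace(0, 20, 24000)
        wave = np.sin(2 * np.pi * t * 120 / 20)   # 120 cycles
        v = wave + 0.5 * t ** 2 - t + 3.0
        out = pp.poly_detrend(v, t, 1.0, order=2)
        assert np.max(np.abs(out.values - wave)) < 0.01
        coef = np.polynomial.polynomial.polyfit(t, wave, 2)
        oracle = wave - np.polynomial.polynomial.polyval(t, coef)
        assert np.max(np.abs(out.values - oracle)) < 1e-9

    def test_residual_orthogonal_to_basis(self):
        rng = np.random.default_rng(3)
        t = np.linspace(0, 10, 500)
        v = rng.standard_normal(500)
        out = pp.poly_detrend(v, t, 1.0, order=2)
        basis = np.vander(t, 3)
        proj = basis.T @ out.values
        assert np.linalg.norm(proj) < 1e-6 * np.linalg.norm(v) * np.linalg.norm(basis)
        assert abs(out.values.mean()) < 1e-6 * v.std()


class TestPipelineProperties:
    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=20, deadline=None)
    def test_cleaning_preserves_length(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(10, 200)
        v = np.abs(rng.normal(10, 6, n))
        t = np.arange(n) / 0.21 / 3600.0
        series = pp.AEEGSeries(values=v, rate=0.21, time_h=t)
        clipped = pp.clip_aeeg_artifacts(series)
        trended = pp.trend_outlier_replace(clipped.values, t, 0.21,
                                           mode="absolute_5uV")
        detrended = pp.poly_detrend(trended.values, t, 0.21)
        assert len(clipped.values) == len(trended.values) == len(detrended.values) == n

    def test_idempotence_on_clean_series(self):
        rng = np.random.default_rng(8)
        t = np.arange(300) / 0.21 / 3600.0
        v = 2.0 * np.sin(2 * np.pi * t / 0.7) + 0.3 * rng.standard_normal(300)
        first = pp.poly_detrend(
            pp.trend_outlier_replace(v, t, 0.21, mode="absolute_5uV").values,
            t, 0.21)
        shifted = first.values + 12.0   # aEEG-like nonnegative level
        series = pp.AEEGSeries(values=shifted, rate=0.21, time_h=t)
        again = pp.poly_detrend(
            pp.trend_outlier_replace(
                pp.clip_aeeg_artifacts(series).values, t, 0.21,
                mode="absolute_5uV").values,
            t, 0.21)
        assert np.max(np.abs(again.values - first.values)) < 1e-9

    def test_cleaning_does_not_destroy_coupling(self, band_mask):
        # expectation over seeds: band coherence with cleaning >= without
        from nvcoh import wtc

        diffs = []
        for seed in range(10):
            spec = sim.CohortSpec(duration_h=6.0, eeg_rate=50.0,
                                  coupling_strength_a=1.0, seed=100 + seed)
            rec = sim.inject_artifacts(sim.simulate_subject(spec, "A", 0),
                                       2.0, seed=seed)
            filt = pp.design_bandpass(fs=rec.eeg_rate)
            env = pp.compute_aeeg(pp.apply_bandpass(rec.eeg, filt), rec.eeg_rate)
            raw = pp.envelope_downsample(env, rec.eeg_rate, rec.scto2_rate)
            ox = pp.preprocess_scto2(rec.scto2, rec.scto2_rate)

            def band_coh(aeeg_values):
                n = min(len(aeeg_values), len(ox.values))
                m = wtc.wavelet_coherence(aeeg_values[:n], ox.values[:n],
                                          1.0 / rec.scto2_rate,
                                          period_limits=(4.0, 90.0))
                return np.nanmean(m.r2[band_mask(m.periods_min)])

            dirty = pp.poly_detrend(raw.values, raw.time_h, raw.rate).values
            clean = pp.preprocess_eeg(rec.eeg, rec.eeg_rate, rec.scto2_rate,
                                      filt=filt).values
            diffs.append(band_coh(clean) - band_coh(dirty))
        assert np.mean(diffs) >= 0.0
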
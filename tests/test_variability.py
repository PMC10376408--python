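from dataclasses import replace

import numpy as np
import pytest
from scipy.signal import periodogram

from cardiovar.core import BeatSeries, ValidationError
from cardiovar.synthetic import make_group_params, simulate_baseline_recording
from cardiovar.variability import (
    HF_BAND,
    LF_BAND,
    BandDefinition,
    ResampledSeries,
    analyze_window,
    lf_hf_ratio,
    resample_beat_series,
    wavelet_band_power,
)


def _uniform_series(values: np.ndarray, fs: float) -> ResampledSeries:
    x = np.asarray(values, dtype=float)
    return ResampledSeries(x - x.mean(), fs, 0.0, mean_value=float(x.mean()))


def _periodogram_band(x: np.ndarray, fs: float, band: BandDefinition) -> float:
    f, pxx = periodogram(x - np.mean(x), fs)
    mask = (f >= band.f_lo) & (f <= band.f_hi)
    return float(np.trapezoid(pxx[mask], f[mask]))


class TestResample:
    def test_uniform_series_preserved_at_grid_points(self):
        times = np.arange(0.0, 60.0, 0.1)
        values = np.sin(times)
        series = BeatSeries(times, values)
        rs = resample_beat_series(series, fs_resample=10.0)
        assert np.allclose(rs.values + rs.mean_value, values[: rs.values.size],
                           atol=1e-9)

    def test_sinusoid_rms_within_one_percent(self, rng):
        # irregular beat-like sampling of a known sinusoid
        times = np.cumsum(rng.uniform(0.12, 0.20, 600))
        values = 3.0 * np.sin(2 * np.pi * 0.3 * times)
        rs = resample_beat_series(BeatSeries(times, values), 10.0)
        rms = np.sqrt(np.mean(rs.values ** 2))
        assert rms == pytest.approx(3.0 / np.sqrt(2.0), rel=0.01)

    def test_short_series_rejected_with_minimum_named(self):
        series = BeatSeries(np.arange(0.0, 10.0, 0.2), np.zeros(50))
        with pytest.raises(ValidationError, match="30"):
            resample_beat_series(series)

    def test_low_rate_rejected(self):
        series = BeatSeries(np.arange(0.0, 60.0, 0.2), np.zeros(300))
        with pytest.raises(ValidationError):
            resample_beat_series(series, fs_resample=2.0)


class TestWaveletBandPower:
    def test_unit_amplitude_convention(self):
        t = np.arange(1800) / 10.0
        x = 2.0 * np.sin(2 * np.pi * 0.3 * t)
        _, power = wavelet_band_power(_uniform_series(x, 10.0), LF_BAND)
        assert power == pytest.approx(2.0, rel=0.05)  # A^2/2 with A = 2

    @pytest.mark.parametrize("f0,amp,band", [
        (0.2, 1.0, LF_BAND), (0.3, 2.0, LF_BAND), (0.45, 1.5, LF_BAND),
        (0.8, 2.0, HF_BAND), (1.2, 1.0, HF_BAND), (1.5, 0.7, HF_BAND),
    ])
    def test_matches_periodogram_band_integral(self, f0, amp, band):
        t = np.arange(2400) / 10.0
        x = amp * np.sin(2 * np.pi * f0 * t)
        _, cwt_power = wavelet_band_power(_uniform_series(x, 10.0), band)
        fft_power = _periodogram_band(x, 10.0, band)
        assert cwt_power == pytest.approx(fft_power, rel=0.05)

    def test_cross_band_confinement(self):
        t = np.arange(1800) / 10.0
        x = np.sin(2 * np.pi * 1.2 * t)
        rs = _uniform_series(x, 10.0)
        _, lf = wavelet_band_power(rs, LF_BAND)
        _, hf = wavelet_band_power(rs, HF_BAND)
        assert lf < 0.01 * hf

    def test_zero_signal_zero_power(self):
        rs = _uniform_series(np.zeros(1800), 10.0)
        _, power = wavelet_band_power(rs, LF_BAND)
        assert power == pytest.approx(0.0, abs=1e-20)

    def test_two_tone_band_additivity(self):
        t = np.arange(2400) / 10.0
        lf_tone = 1.5 * np.sin(2 * np.pi * 0.3 * t)
        hf_tone = 0.8 * np.sin(2 * np.pi * 1.2 * t)
        rs = _uniform_series(lf_tone + hf_tone, 10.0)
        _, lf = wavelet_band_power(rs, LF_BAND)
        _, hf = wavelet_band_power(rs, HF_BAND)
        assert lf == pytest.approx(1.5 ** 2 / 2, rel=0.05)
        assert hf == pytest.approx(0.8 ** 2 / 2, rel=0.05)

    def test_scale_invariance(self):
        t = np.arange(1800) / 10.0
        x = np.sin(2 * np.pi * 0.3 * t)
        _, p1 = wavelet_band_power(_uniform_series(x, 10.0), LF_BAND)
        _, p9 = wavelet_band_power(_uniform_series(3.0 * x, 10.0), LF_BAND)
        assert p9 == pytest.approx(9.0 * p1, rel=1e-6)

    def test_band_above_nyquist_rejected(self):
        rs = _uniform_series(np.zeros(1800), 3.0)
        with pytest.raises(ValidationError, match="Nyquist"):
            wavelet_band_power(rs, HF_BAND)

    def test_too_few_cycles_rejected(self):
        rs = _uniform_series(np.zeros(200), 10.0)  # 20 s < 5 / 0.15 Hz
        with pytest.raises(ValidationError, match="cycles"):
            wavelet_band_power(rs, LF_BAND)


class TestLfHfRatio:
    def test_equal_powers(self):
        assert lf_hf_ratio(2.0, 2.0) == 1.0

    def test_zero_lf(self):
        assert lf_hf_ratio(0.0, 5.0) == 0.0

    @pytest.mark.parametrize("h", [0.1, 1.0, 42.0])
    def test_scale_invariance_at_dox8_ratio(self, h):
        assert lf_hf_ratio(0.54 * h, h) == pytest.approx(0.54)

    def test_undefined_below_epsilon(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(lf_hf_ratio(1.0, 0.0))

    def test_negative_power_rejected(self):
        with pytest.raises(ValidationError):
            lf_hf_ratio(-1.0, 1.0)


class TestAnalyzeWindow:
    def test_recovers_ctl_calibrated_ratio(self, ctl_baseline):
        from cardiovar.beats import detect_r_peaks, extract_bp_beats, rr_and_hr

        peaks = detect_r_peaks(ctl_baseline.channel("ecg"))
        _, hr = rr_and_hr(peaks)
        press = extract_bp_beats(ctl_baseline.channel("abp"), peaks)
        idx = analyze_window(press.series("sbp"), hr)
        assert idx.ratio_defined
        assert idx.lf_hf_ratio == pytest.approx(1.14, rel=0.10)

    def test_symmetric_amplitudes_give_unit_ratio(self, rng):
        # matched LF/HF content constructed directly at the beat level
        times = np.cumsum(rng.uniform(0.14, 0.18, 1200))
        lf = 2.0 * np.sin(2 * np.pi * 0.3 * times)
        hf = 2.0 * np.sin(2 * np.pi * 1.2 * times)
        idx = analyze_window(BeatSeries(times, 150.0 + lf),
                             BeatSeries(times, 379.0 + hf))
        assert idx.lf_hf_ratio == pytest.approx(1.0, rel=0.05)

    def test_zero_hf_flags_undefined(self, rng):
        times = np.cumsum(rng.uniform(0.14, 0.18, 1200))
        lf = 2.0 * np.sin(2 * np.pi * 0.3 * times)
        idx = analyze_window(BeatSeries(times, 150.0 + lf),
                             BeatSeries(times, np.full(times.size, 379.0)))
        assert not idx.ratio_defined
        assert np.isnan(idx.lf_hf_ratio)

    def test_window_defaults_to_180s(self, rng):
        times = np.cumsum(rng.uniform(0.14, 0.18, 2000))
        sbp = BeatSeries(times, 150.0 + np.sin(2 * np.pi * 0.3 * times))
        hr = BeatSeries(times, 379.0 + np.sin(2 * np.pi * 1.2 * times))
        idx = analyze_window(sbp, hr)
        assert idx.window[1] - idx.window[0] == pytest.approx(180.0)


class TestParameterRecovery:
    def test_mean_ratio_across_20_seeds_within_10_percent(self):
        """Calibrated LF/HF is recovered on average across seeded subjects."""
        from cardiovar.beats import detect_r_peaks, extract_bp_beats, rr_and_hr

        params = make_group_params("CTL")
        ratios = []
        for seed in range(20):
            bundle = simulate_baseline_recording(
                replace(params, seed=seed), 180.0, 250.0)
            peaks = detect_r_peaks(bundle.channel("ecg"))
            _, hr = rr_and_hr(peaks)
            press = extract_bp_beats(bundle.channel("abp"), peaks)
            idx = analyze_window(press.series("sbp"), hr)
            ratios.append(idx.lf_hf_ratio)
        assert np.mean(ratios) == pytest.approx(params.lf_hf_target, rel=0.10)
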
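import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiovar.beats import (
    detect_r_peaks,
    extract_bp_beats,
    respiratory_frequency,
    rr_and_hr,
)
from cardiovar.core import ValidationError, Waveform
from cardiovar.synthetic import simulate_baseline_recording


def _gaussian_train(rr_s: float, duration_s: float, fs: float) -> Waveform:
    n = int(duration_s * fs)
    t = np.arange(n) / fs
    x = np.zeros(n)
    for tb in np.arange(0.0, duration_s, rr_s):
        x += np.exp(-0.5 * ((t - tb) / 0.008) ** 2)
    return Waveform("ecg", x, fs, units="mV")


class TestDetectRPeaks:
    def test_clean_train_rr_200ms(self):
        ecg = _gaussian_train(0.2, 60.0, 1000.0)
        peaks = detect_r_peaks(ecg)
        assert abs(peaks.size - 300) <= 1
        _, hr = rr_and_hr(peaks)
        assert np.mean(hr.values) == pytest.approx(300.0, rel=1e-3)

    def test_recall_and_precision_on_generator(self, ctl_baseline):
        truth = ctl_baseline.ground_truth["beat_times"]
        peaks = detect_r_peaks(ctl_baseline.channel("ecg"))
        d_truth = np.abs(truth[:, None] - peaks[None, :]).min(axis=1)
        d_det = np.abs(truth[:, None] - peaks[None, :]).min(axis=0)
        recall = np.mean(d_truth < 0.010)
        precision = np.mean(d_det < 0.010)
        assert recall >= 0.99
        assert precision >= 0.99

    def test_flatline_returns_empty_with_warning(self):
        flat = Waveform("ecg", np.zeros(5000), 1000.0)
        with pytest.warns(UserWarning):
            peaks = detect_r_peaks(flat)
        assert peaks.size == 0

    def test_noise_only_returns_empty_with_warning(self, rng):
        noise = Waveform("ecg", 0.02 * rng.standard_normal(5000), 1000.0)
        with pytest.warns(UserWarning):
            peaks = detect_r_peaks(noise)
        assert peaks.size == 0

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            detect_r_peaks(Waveform("ecg", np.zeros(500), 1000.0))

    def test_bad_rate_bounds_rejected(self, ctl_baseline):
        with pytest.raises(ValidationError):
            detect_r_peaks(ctl_baseline.channel("ecg"), min_rate_bpm=600,
                           max_rate_bpm=100)


class TestRrAndHr:
    def test_rr_200ms_gives_hr_300(self):
        rr, hr = rr_and_hr(np.array([0.0, 0.2, 0.4, 0.6]))
        assert np.allclose(rr.values, 200.0)
        assert np.allclose(hr.values, 300.0)

    def test_ctl_mean_rr_matches_printed_hr(self):
        # 60000 / 158.31 ms ~ 379 bpm
        rr, hr = rr_and_hr(np.array([0.0, 0.15831, 2 * 0.15831]))
        assert hr.values[0] == pytest.approx(379.0, abs=0.05)

    def test_single_peak_errors(self):
        with pytest.raises(ValidationError):
            rr_and_hr(np.array([1.0]))

    def test_duality_holds_exactly(self, ctl_baseline):
        peaks = detect_r_peaks(ctl_baseline.channel("ecg"))
        rr, hr = rr_and_hr(peaks)
        # hr is exactly 60000/rr; the re-multiplied product can differ from
        # 60000 by at most one rounding (IEEE-754 division + multiplication)
        assert np.array_equal(hr.values, 60000.0 / rr.values)
        assert np.max(np.abs(hr.values * rr.values - 60000.0)) <= 60000.0 * 2 ** -52

    @given(st.lists(st.floats(min_value=0.05, max_value=2.0), min_size=2,
                    max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_duality_property(self, intervals):
        times = np.cumsum([0.0] + intervals)
        rr, hr = rr_and_hr(times)
        assert np.array_equal(hr.values, 60000.0 / rr.values)
        assert np.max(np.abs(hr.values * rr.values - 60000.0)) <= 60000.0 * 2 ** -52
        assert np.array_equal(rr.times, times[1:])


class TestExtractBpBeats:
    def test_known_oscillation_levels(self):
        # square-ish oscillation between CTL diastolic and systolic levels
        fs = 1000.0
        t = np.arange(int(2.0 * fs)) / fs
        x = np.where((t % 0.2) < 0.1, 150.0, 111.0)
        beats = extract_bp_beats(Waveform("abp", x, fs), np.arange(0.0, 2.01, 0.2))
        assert np.allclose(beats.sbp, 150.0)
        assert np.allclose(beats.dbp, 111.0)

    def test_constant_pressure(self):
        w = Waveform("abp", np.full(2000, 120.0), 1000.0)
        beats = extract_bp_beats(w, np.array([0.0, 0.5, 1.0, 1.5]))
        assert np.allclose(beats.sbp, 120.0)
        assert np.allclose(beats.dbp, 120.0)
        assert np.allclose(beats.mbp, 120.0)

    def test_ordering_invariant_on_generator(self, ctl_baseline):
        peaks = detect_r_peaks(ctl_baseline.channel("ecg"))
        beats = extract_bp_beats(ctl_baseline.channel("abp"), peaks)
        assert np.all(beats.sbp >= beats.mbp)
        assert np.all(beats.mbp >= beats.dbp)

    def test_recovers_per_beat_systolic_truth(self, ctl_baseline):
        gt = ctl_baseline.ground_truth
        beats = extract_bp_beats(ctl_baseline.channel("abp"), gt["beat_times"])
        n = min(len(beats), gt["sbp_values"].size)
        err = np.abs(beats.sbp[:n] - gt["sbp_values"][:n])
        # within waveform noise plus discretization of the pulse peak
        assert np.percentile(err, 95) < 5 * ctl_baseline.ground_truth[
            "params"].noise.bp_level_mmHg + 0.5

    def test_tiny_window_skipped_with_warning(self):
        w = Waveform("abp", np.full(2000, 120.0), 1000.0)
        with pytest.warns(UserWarning, match="skipped"):
            beats = extract_bp_beats(w, np.array([0.0, 0.001, 1.0, 1.5]))
        assert len(beats) == 2

    def test_beats_outside_span_rejected(self):
        w = Waveform("abp", np.full(2000, 120.0), 1000.0)
        with pytest.raises(ValidationError):
            extract_bp_beats(w, np.array([0.0, 5.0]))


class TestRespiratoryFrequency:
    def _sine(self, freq_hz: float, duration_s: float = 60.0, fs: float = 250.0):
        t = np.arange(int(duration_s * fs)) / fs
        return Waveform("tracheal", 2.0 + 2.0 * np.sin(2 * np.pi * freq_hz * t), fs)

    def test_one_hz_gives_60_cpm(self):
        rf = respiratory_frequency(self._sine(1.0))
        assert np.allclose(rf.values[rf.quality], 60.0, atol=0.5)

    def test_72_5_cpm_recovered(self):
        rf = respiratory_frequency(self._sine(72.5 / 60.0))
        assert np.allclose(rf.values[rf.quality], 72.5, atol=0.5)

    def test_noisy_generator_trace_within_1_cpm(self, ctl_baseline):
        rf = respiratory_frequency(ctl_baseline.channel("tracheal"))
        target = ctl_baseline.ground_truth["rf_cpm"]
        assert np.all(np.abs(rf.values[rf.quality] - target) < 1.0)

    def test_aperiodic_input_flagged(self, rng):
        w = Waveform("tracheal", rng.standard_normal(15000), 250.0)
        rf = respiratory_frequency(w)
        assert rf.quality is not None  # flags exist even if noise looks periodic

    def test_flat_input_gets_quality_false(self):
        w = Waveform("tracheal", np.zeros(5000), 250.0)
        with pytest.warns(UserWarning):
            rf = respiratory_frequency(w)
        assert not rf.quality.any()

    def test_window_minimum_enforced(self):
        with pytest.raises(ValidationError):
            respiratory_frequency(self._sine(1.0), window_s=5.0)


class TestDefaultNoiseRecovery:
    def test_detector_recovery_at_default_noise(self):
        from cardiovar.synthetic import make_group_params

        params = make_group_params("DOX20", seed=9)
        bundle = simulate_baseline_recording(params, 180.0, 500.0, seed=9)
        peaks = detect_r_peaks(bundle.channel("ecg"))
        truth = bundle.ground_truth["beat_times"]
        d = np.abs(truth[:, None] - peaks[None, :]).min(axis=1)
        assert np.mean(d < 0.010) >= 0.99
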
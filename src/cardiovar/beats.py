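"""Waveform -> beat-indexed series conversion.

R-peak detection follows the classic band-pass / squared-derivative /
moving-integration recipe with an adaptive amplitude threshold and a
refractory period derived from the physiological maximum rate.  Detected
peaks are mapped back to the raw-signal maximum and refined to
sub-sample precision with a least-squares parabola, which keeps the
beat-to-beat timing jitter far below the sampling interval (important:
RR jitter aliases directly into HF heart-rate band power).
"""

from __future__ import annotations

import math
import warnings
from typing import Tuple

import numpy as np
from scipy import signal

from .core import BeatSeries, PressureBeats, ValidationError, Waveform


def _bandpass(x: np.ndarray, fs: float, f_lo: float = 5.0, f_hi: float = 30.0) -> np.ndarray:
    nyq = fs / 2.0
    hi = min(f_hi, 0.9 * nyq)
    lo = min(f_lo, 0.5 * hi)
    sos = signal.butter(3, [lo / nyq, hi / nyq], btype="band", output="sos")
    return signal.sosfiltfilt(sos, x)


def _refine_peak_time(x: np.ndarray, idx: int, fs: float, half_width_s: float = 0.006) -> float:
    """Sub-sample peak location via a least-squares quadratic fit."""
    h = max(2, int(round(half_width_s * fs)))
    i0, i1 = max(0, idx - h), min(x.size, idx + h + 1)
    w = np.arange(i0, i1) - idx
    y = x[i0:i1]
    if w.size < 3:
        return idx / fs
    a, b, _ = np.polyfit(w, y, 2)
    if a >= 0:                      # not concave: keep the grid maximum
        return idx / fs
    delta = -b / (2.0 * a)
    delta = float(np.clip(delta, -1.0, 1.0))
    return (idx + delta) / fs


def detect_r_peaks(
    ecg: Waveform,
    min_rate_bpm: float = 100.0,
    max_rate_bpm: float = 600.0,
) -> np.ndarray:
    """Detect R-wave times (seconds, absolute) in an ECG waveform.

    Returns an empty array (with a warning) when no QRS-like activity is
    found rather than failing.
    """
    if not (0 < min_rate_bpm < max_rate_bpm):
        raise ValidationError("need 0 < min_rate_bpm < max_rate_bpm")
    if ecg.duration < 2.0:
        raise ValidationError("ECG must be at least 2 s long")
    fs = ecg.sampling_rate
    x = ecg.samples

    filt = _bandpass(x, fs)
    det = np.gradient(filt) ** 2
    win = max(1, int(round(0.04 * fs)))          # ~QRS width integration window
    det = np.convolve(det, np.ones(win) / win, mode="same")

    refractory = max(1, int(round(60.0 / max_rate_bpm * fs)))
    cand, _ = signal.find_peaks(det, distance=refractory)
    if cand.size == 0 or float(np.max(det)) <= 0.0:
        warnings.warn("no R peaks found (flat or empty detection function)", stacklevel=2)
        return np.empty(0)

    heights = det[cand]
    strong = float(np.percentile(heights, 95))
    # 25th percentile: robust noise floor even when QRS bumps occupy a
    # third of the trace at high heart rates
    background = float(np.percentile(det, 25))
    if strong < 8.0 * max(background, 1e-30):
        warnings.warn("no QRS-like activity above the noise floor", stacklevel=2)
        return np.empty(0)
    keep = cand[heights > 0.2 * strong]

    # map back to the raw-signal peak and refine to sub-sample precision
    snap = max(1, int(round(0.02 * fs)))
    times = []
    peak_amps = []
    last_idx = -10 * refractory
    for c in keep:
        i0, i1 = max(0, c - snap), min(x.size, c + snap + 1)
        idx = i0 + int(np.argmax(x[i0:i1]))
        if idx - last_idx < refractory:
            continue
        last_idx = idx
        peak_amps.append(x[idx])
        times.append(_refine_peak_time(x, idx, fs))

    # amplitude significance: R waves must stand well above the robust
    # noise scale of the raw trace, otherwise this is noise, not ECG
    center = float(np.median(x))
    noise_scale = 1.4826 * float(np.median(np.abs(x - center)))
    if float(np.median(peak_amps)) - center < 5.0 * noise_scale:
        warnings.warn("no QRS-like activity above the noise floor", stacklevel=2)
        return np.empty(0)

    out = ecg.start_time + np.asarray(times)
    return np.clip(out, ecg.start_time, ecg.end_time)


def rr_and_hr(peak_times: np.ndarray) -> Tuple[BeatSeries, BeatSeries]:
    """RR intervals (ms) and heart rate (bpm), stamped at the later beat.

    ``hr[i] * rr[i] == 60000`` holds exactly for every beat.
    """
    peak_times = np.asarray(peak_times, dtype=float)
    if peak_times.size < 2:
        raise ValidationError("need at least 2 peaks to form RR intervals")
    rr_ms = np.diff(peak_times) * 1000.0
    if np.any(rr_ms <= 0):
        raise ValidationError("peak times must be strictly increasing")
    hr_bpm = 60000.0 / rr_ms
    t = peak_times[1:]
    return (
        BeatSeries(t, rr_ms, kind="RR", units="ms"),
        BeatSeries(t, hr_bpm, kind="HR", units="bpm"),
    )


def extract_bp_beats(abp: Waveform, beat_times: np.ndarray) -> PressureBeats:
    """Per-beat systolic / diastolic / mean pressure over [t_i, t_{i+1}).

    mBP is the true time-average of the pressure over the beat window
    (not the diastolic + pulse-pressure/3 approximation).  The final
    partial beat is dropped; windows with < 3 samples are skipped.
    """
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.size < 2:
        raise ValidationError("need at least 2 beat times")
    if beat_times[0] < abp.start_time - 1e-9 or beat_times[-1] > abp.end_time + 1e-9:
        raise ValidationError("beat times fall outside the pressure waveform span")
    fs = abp.sampling_rate
    x = abp.samples
    t0_rec = abp.start_time

    times, sbp, dbp, mbp = [], [], [], []
    skipped = 0
    for i in range(beat_times.size - 1):
        i0 = int(math.ceil((beat_times[i] - t0_rec) * fs))
        i1 = int(math.ceil((beat_times[i + 1] - t0_rec) * fs))
        i0, i1 = max(0, i0), min(x.size, i1)
        if i1 - i0 < 3:
            skipped += 1
            continue
        seg = x[i0:i1]
        times.append(beat_times[i])
        sbp.append(float(np.max(seg)))
        dbp.append(float(np.min(seg)))
        mbp.append(float(np.mean(seg)))
    if skipped:
        warnings.warn(f"skipped {skipped} beat window(s) with < 3 samples", stacklevel=2)
    if not times:
        raise ValidationError("no usable beat windows in the pressure waveform")
    return PressureBeats(np.asarray(times), np.asarray(sbp), np.asarray(dbp),
                         np.asarray(mbp))


def respiratory_frequency(tracheal: Waveform, window_s: float = 10.0) -> BeatSeries:
    """Respiratory frequency (cycles/min) per non-overlapping window.

    Cycles are detected as peaks with prominence >= 20% of the window's
    amplitude range; the rate is the dominant-cycle count per second
    (cycle count over the spanned time) times 60.  Windows where no
    periodicity is found are flagged ``quality=False`` (value 0).
    """
    if window_s < 10.0:
        raise ValidationError("window_s must be >= 10 s")
    fs = tracheal.sampling_rate
    n_win = int(round(window_s * fs))
    n_windows = tracheal.samples.size // n_win
    if n_windows == 0:
        raise ValidationError("waveform shorter than one analysis window")

    centers, rates, quality = [], [], []
    for k in range(n_windows):
        seg = tracheal.samples[k * n_win: (k + 1) * n_win]
        rng_amp = float(np.max(seg) - np.min(seg))
        t_center = tracheal.start_time + (k + 0.5) * window_s
        if rng_amp <= 0:
            centers.append(t_center); rates.append(0.0); quality.append(False)
            continue
        peaks, _ = signal.find_peaks(seg, prominence=0.2 * rng_amp)
        if peaks.size < 2:
            centers.append(t_center); rates.append(0.0); quality.append(False)
            continue
        span_s = (peaks[-1] - peaks[0]) / fs
        rate_cpm = 60.0 * (peaks.size - 1) / span_s
        centers.append(t_center); rates.append(rate_cpm); quality.append(True)
    if not any(quality):
        warnings.warn("no periodic respiratory activity detected", stacklevel=2)
    return BeatSeries(np.asarray(centers), np.asarray(rates), kind="RF",
                      units="cpm", quality=np.asarray(quality))
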
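"""Wavelet time-frequency analysis of beat series (LF / HF band power).

Beat series are cubic-interpolated onto a uniform grid, transformed with
an analytic Morlet continuous wavelet transform (centre angular
frequency ``omega0 = 6``, i.e. centre frequency ``6 / (2*pi)``), and
band power is obtained by integrating the squared magnitude over the
scales whose equivalent Fourier frequency falls inside the band.

Normalization is fixed so that a unit-amplitude in-band sinusoid yields
a mean band power of exactly 0.5 (A^2 / 2 convention, matching a
periodogram band integral).  Because discrete CWT power conventions vary
between implementations, the constant is obtained by calibrating the
identical code path against a unit sinusoid at the band's geometric
centre; the constant is cached per (band, rate, scale-resolution).

Band defaults follow the rat convention: LF 0.15-0.6 Hz measured on the
systolic-pressure series, HF 0.6-2.0 Hz on the heart-rate series.
"""

from __future__ import annotations

import functools
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.interpolate import CubicSpline

from .core import BeatSeries, ValidationError

#: below this band power the LF/HF ratio is reported as undefined
RATIO_EPS = 1e-12

_OMEGA0 = 6.0
#: scale -> Fourier period factor for the Morlet wavelet
_FOURIER_FACTOR = 4.0 * math.pi / (_OMEGA0 + math.sqrt(2.0 + _OMEGA0 ** 2))


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band tied to its source series."""

    name: str
    f_lo: float
    f_hi: float
    source: str

    def __post_init__(self):
        if not (0 < self.f_lo < self.f_hi):
            raise ValidationError("band requires 0 < f_lo < f_hi")


LF_BAND = BandDefinition("LF", 0.15, 0.6, "SBP")
HF_BAND = BandDefinition("HF", 0.6, 2.0, "HR")


@dataclass
class ResampledSeries:
    """A beat series interpolated onto a uniform grid, mean removed."""

    values: np.ndarray
    fs: float
    start_time: float
    mean_value: float
    mean_removed: bool = True

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("resampled series contains non-finite values")

    @property
    def duration(self) -> float:
        return self.values.size / self.fs


@dataclass
class AutonomicIndices:
    """LF power, HF power and their ratio for one analysis window."""

    window: Tuple[float, float]
    lf_power: float
    hf_power: float
    lf_hf_ratio: float
    ratio_defined: bool = True


def resample_beat_series(
    series: BeatSeries, fs_resample: float = 10.0
) -> ResampledSeries:
    """Cubic-interpolate a beat series onto a uniform grid.

    The grid never extends beyond the first/last beat (no extrapolation)
    and the series mean is removed.
    """
    if fs_resample < 4.0:
        raise ValidationError("fs_resample must be >= 4 Hz (2x the HF upper edge)")
    if len(series) < 4 or series.span < 30.0:
        raise ValidationError(
            f"series spans {series.span:.1f} s; need >= 30 s and >= 4 beats"
        )
    t0, t1 = series.times[0], series.times[-1]
    n = int(math.floor((t1 - t0) * fs_resample)) + 1
    grid = t0 + np.arange(n) / fs_resample
    spline = CubicSpline(series.times, series.values)
    vals = spline(grid)
    mean = float(np.mean(vals))
    return ResampledSeries(vals - mean, fs_resample, t0, mean_value=mean)


def _morlet_cwt(x: np.ndarray, dt: float, scales: np.ndarray) -> np.ndarray:
    """Analytic Morlet CWT (reflect-padded), rows = scales."""
    n = x.size
    # reflect-pad a full copy on each side, round up to a power of two
    pad = np.concatenate([x[::-1], x, x[::-1]])
    nfft = 1 << int(math.ceil(math.log2(pad.size)))
    xhat = np.fft.fft(pad, nfft)
    omega = 2.0 * np.pi * np.fft.fftfreq(nfft, dt)
    W = np.empty((scales.size, n), dtype=complex)
    norm0 = math.pi ** -0.25
    pos = omega > 0
    for j, s in enumerate(scales):
        psi_hat = np.zeros(nfft)
        psi_hat[pos] = (
            norm0 * math.sqrt(2.0 * math.pi * s / dt)
            * np.exp(-0.5 * (s * omega[pos] - _OMEGA0) ** 2)
        )
        full = np.fft.ifft(xhat * psi_hat)
        W[j] = full[n: 2 * n]
    return W


def _band_scales(f_lo: float, f_hi: float, dj: float) -> np.ndarray:
    s_min = 1.0 / (_FOURIER_FACTOR * f_hi)
    s_max = 1.0 / (_FOURIER_FACTOR * f_lo)
    n = int(math.floor(math.log2(s_max / s_min) / dj)) + 1
    return s_min * 2.0 ** (dj * np.arange(n))


def _raw_band_power(x: np.ndarray, fs: float, f_lo: float, f_hi: float,
                    dj: float) -> Tuple[np.ndarray, np.ndarray]:
    """Un-calibrated band power time course and its cone-of-influence mask."""
    dt = 1.0 / fs
    scales = _band_scales(f_lo, f_hi, dj)
    W = _morlet_cwt(x, dt, scales)
    power = dj * dt * np.sum(np.abs(W) ** 2 / scales[:, None], axis=0)
    coi_s = math.sqrt(2.0) * scales[-1]
    t = np.arange(x.size) * dt
    mask = (t >= coi_s) & (t <= t[-1] - coi_s)
    return power, mask


@functools.lru_cache(maxsize=64)
def _calibration_constant(f_lo: float, f_hi: float, fs: float, dj: float) -> float:
    """Scale factor making a unit in-band sinusoid read 0.5 mean power."""
    f0 = math.sqrt(f_lo * f_hi)
    duration = max(20.0 / f_lo, 60.0)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    x = np.sin(2.0 * np.pi * f0 * t)
    power, mask = _raw_band_power(x, fs, f_lo, f_hi, dj)
    ref = float(np.mean(power[mask])) if mask.any() else float(np.mean(power))
    if ref <= 0:
        raise RuntimeError("wavelet calibration failed")
    return 0.5 / ref


def wavelet_band_power(
    series: ResampledSeries,
    band: BandDefinition,
    dj: float = 0.05,
) -> Tuple[np.ndarray, float]:
    """Band power time course and its cone-of-influence-excluded mean.

    Returns ``(power_timecourse, mean_power)`` in the squared units of
    the input series; a sinusoid of amplitude A inside the band yields a
    mean power of ``A**2 / 2``.
    """
    fs = series.fs
    if band.f_hi >= fs / 2.0:
        raise ValidationError(
            f"band upper edge {band.f_hi} Hz is not below Nyquist ({fs / 2:.2f} Hz)"
        )
    if series.duration < 5.0 / band.f_lo:
        raise ValidationError(
            f"series covers {series.duration:.1f} s; need >= 5 cycles of "
            f"{band.f_lo} Hz ({5.0 / band.f_lo:.1f} s)"
        )
    x = series.values - (0.0 if series.mean_removed else np.mean(series.values))
    power, mask = _raw_band_power(x, fs, band.f_lo, band.f_hi, dj)
    k = _calibration_constant(band.f_lo, band.f_hi, fs, dj)
    power = k * power
    if not mask.any():
        warnings.warn("series too short to exclude the cone of influence", stacklevel=2)
        mask = np.ones(power.size, dtype=bool)
    return power, float(np.mean(power[mask]))


def lf_hf_ratio(lf_power: float, hf_power: float) -> float:
    """LF/HF balance; NaN (with a warning) when HF power is ~zero."""
    if lf_power < 0 or hf_power < 0:
        raise ValidationError("band powers must be non-negative")
    if hf_power <= RATIO_EPS:
        warnings.warn("HF power below epsilon; LF/HF undefined", stacklevel=2)
        return float("nan")
    return lf_power / hf_power


def analyze_window(
    sbp: BeatSeries,
    hr: BeatSeries,
    window: Optional[Tuple[float, float]] = None,
    window_s: float = 180.0,
    lf_band: BandDefinition = LF_BAND,
    hf_band: BandDefinition = HF_BAND,
    fs_resample: float = 10.0,
) -> AutonomicIndices:
    """Compute LF (from SBP), HF (from HR) and LF/HF for one window.

    When ``window`` is None the first ``window_s`` seconds jointly
    covered by both series are used.
    """
    if window is None:
        t0 = max(sbp.times[0], hr.times[0])
        window = (t0, t0 + window_s)
    t0, t1 = window
    sbp_w = sbp.slice(t0, t1 + 1e-9)
    hr_w = hr.slice(t0, t1 + 1e-9)
    _, lf_power = wavelet_band_power(resample_beat_series(sbp_w, fs_resample), lf_band)
    _, hf_power = wavelet_band_power(resample_beat_series(hr_w, fs_resample), hf_band)
    if hf_power <= RATIO_EPS:
        return AutonomicIndices(window, lf_power, hf_power, float("nan"),
                                ratio_defined=False)
    return AutonomicIndices(window, lf_power, hf_power, lf_power / hf_power)
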
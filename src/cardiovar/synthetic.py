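"""Synthetic cohort generator with known ground truth.

Every quantity the analysis pipeline estimates (heart rate, per-beat
pressures, LF/HF band powers, baroreflex gain, respiratory-rate steps,
collagen pixel fraction, catecholamine levels) is *programmed* here, so
each downstream stage has an exact recovery oracle.  Group defaults are
calibrated to the study's printed group means and SEMs; fields the study
report leaves ambiguous are marked in ``PROVENANCE``.

Signal model
------------
* ECG: a train of Gaussian R waves whose instantaneous rate is
  ``hr + hf_amp * sin(2*pi*hf_freq*t)`` plus per-beat noise.  Beat times
  are constructed implicitly so that the beat-to-beat heart rate
  ``60 / RR`` sampled at each beat equals the target rate exactly.
* Arterial pressure: one pulse wave per beat (half-cosine upstroke,
  exponential decay) with per-beat systolic level
  ``sbp + lf_amp * sin(2*pi*lf_freq*t)`` plus noise, diastolic ``dbp``.
* Tracheal pressure: a sinusoid at the respiratory rate (cpm / 60).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .core import (
    STUDY_GROUPS,
    Event,
    RecordingBundle,
    ValidationError,
    Waveform,
)

# --------------------------------------------------------------------------
# Printed group statistics (mean, SEM) used to calibrate the generator.
# Group sizes: CTL n=6, every DOX arm n=8.
# --------------------------------------------------------------------------

GROUP_SIZES: Dict[str, int] = {"CTL": 6, "DOX8": 8, "DOX16": 8, "DOX20": 8}

#: (mean, sem) per group per calibration variable.  ``None`` sem means the
#: source did not report one and a conservative stand-in is used.
GROUP_STATS: Dict[str, Dict[str, Tuple[float, float]]] = {
    "CTL": {
        "hr_bpm": (379.0, 22.0),
        "sbp_mmHg": (150.0, 5.3),
        "dbp_mmHg": (111.0, 3.9),
        "brg_bpm_per_mmHg": (0.28, 0.02),
        "delta_rf_cpm": (8.4, 1.1),
        "lf_hf_ratio": (1.14, 0.19),
        "hf_power_bpm2": (1.13, 0.17),
        "collagen_fraction_pct": (59.9, 0.95),
        "adrenaline_ng_ml": (19.77, 2.044),
        "noradrenaline_ng_ml": (76.20, 11.89),
        "dopamine_ng_ml": (669.5, 145.2),
    },
    "DOX8": {
        "hr_bpm": (365.0, 20.0),        # not reported (no significant change); assumed
        "sbp_mmHg": (136.0, 4.7),
        "dbp_mmHg": (100.0, 4.7),       # reported value is a copy error; interpolated
        "brg_bpm_per_mmHg": (0.37, 0.04),
        "delta_rf_cpm": (12.5, 1.0),
        "lf_hf_ratio": (0.54, 0.16),
        "hf_power_bpm2": (2.39, 0.6),   # derived: CTL LF power / group LF-HF ratio
        "collagen_fraction_pct": (55.04, 0.25),
        "adrenaline_ng_ml": (28.91, 6.827),
        "noradrenaline_ng_ml": (73.96, 14.24),
        "dopamine_ng_ml": (615.2, 144.8),
    },
    "DOX16": {
        "hr_bpm": (290.0, 26.0),
        "sbp_mmHg": (107.0, 9.2),
        "dbp_mmHg": (84.0, 9.2),
        "brg_bpm_per_mmHg": (0.49, 0.06),
        "delta_rf_cpm": (15.4, 1.9),
        "lf_hf_ratio": (0.69, 0.39),
        "hf_power_bpm2": (1.87, 0.5),   # derived as for DOX8
        "collagen_fraction_pct": (65.8, 2.36),
        "adrenaline_ng_ml": (28.16, 5.302),
        "noradrenaline_ng_ml": (111.2, 24.75),
        "dopamine_ng_ml": (707.0, 145.9),
    },
    "DOX20": {
        "hr_bpm": (242.0, 25.0),
        "sbp_mmHg": (104.9, 7.2),
        "dbp_mmHg": (73.0, 6.6),
        "brg_bpm_per_mmHg": (0.24, 0.3),
        "delta_rf_cpm": (7.2, 0.8),
        "lf_hf_ratio": (0.21, 0.12),
        "hf_power_bpm2": (22.23, 11.18),
        "collagen_fraction_pct": (65.7, 1.88),
        "adrenaline_ng_ml": (22.20, 11.33),
        "noradrenaline_ng_ml": (125.6, 62.80),
        "dopamine_ng_ml": (623.4, 287.6),
    },
}

#: Provenance notes for calibration values that are not direct read-offs.
PROVENANCE = {
    "DOX8.hr_bpm": "assumed (between CTL and DOX16; reported as non-significant change)",
    "DOX8.dbp_mmHg": "assumed (reported dBP duplicates sBP; scaled from CTL by the sBP ratio)",
    "DOX8.hf_power_bpm2": "derived from CTL LF power and the group LF/HF ratio",
    "DOX16.hf_power_bpm2": "derived from CTL LF power and the group LF/HF ratio",
    "rf_basal_cpm": "assumed 60 cpm for all groups (baseline respiratory rate not reported)",
}

#: Default basal respiratory rate (cycles/min) for every group.
RF_BASAL_DEFAULT = 60.0


@dataclass
class NoiseLevels:
    """Per-channel noise magnitudes (standard deviations)."""

    ecg_mV: float = 0.01            # additive broadband noise on the ECG trace
    hr_bpm: float = 0.2             # per-beat jitter of the instantaneous rate
    bp_level_mmHg: float = 0.3      # per-beat jitter of systolic/diastolic levels
    bp_wave_mmHg: float = 0.1       # additive noise on the pressure trace
    tracheal_cmH2O: float = 0.05    # additive noise on tracheal pressure

    @classmethod
    def zero(cls) -> "NoiseLevels":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)

    def scaled(self, factor: float) -> "NoiseLevels":
        return NoiseLevels(*(factor * v for v in (
            self.ecg_mV, self.hr_bpm, self.bp_level_mmHg,
            self.bp_wave_mmHg, self.tracheal_cmH2O)))


@dataclass
class SubjectParams:
    """Ground-truth parameters for one synthetic animal."""

    group: str = "CTL"
    hr_bpm: float = 379.0
    sbp_mmHg: float = 150.0
    dbp_mmHg: float = 111.0
    lf_amp_mmHg: float = 1.60
    lf_freq_Hz: float = 0.3
    hf_amp_bpm: float = 1.50
    hf_freq_Hz: float = 1.2
    brg_bpm_per_mmHg: float = 0.28
    rf_basal_cpm: float = RF_BASAL_DEFAULT
    rf_stim_cpm: float = RF_BASAL_DEFAULT + 8.4
    collagen_fraction_pct: float = 59.9
    adrenaline_ng_ml: float = 19.77
    noradrenaline_ng_ml: float = 76.20
    dopamine_ng_ml: float = 669.5
    noise: NoiseLevels = field(default_factory=NoiseLevels)
    seed: int = 0

    def __post_init__(self):
        if self.group not in STUDY_GROUPS:
            raise ValidationError(
                f"unknown group label {self.group!r}; valid labels: {STUDY_GROUPS}"
            )
        if not self.hr_bpm > 0:
            raise ValidationError("hr_bpm must be > 0")
        if not self.sbp_mmHg > self.dbp_mmHg:
            raise ValidationError("sbp_mmHg must exceed dbp_mmHg")
        if not (0.15 <= self.lf_freq_Hz <= 0.6):
            raise ValidationError("lf_freq_Hz must sit inside the LF band [0.15, 0.6] Hz")
        if not (0.6 < self.hf_freq_Hz <= 2.0):
            raise ValidationError("hf_freq_Hz must sit inside the HF band (0.6, 2.0] Hz")
        if not (0.0 <= self.collagen_fraction_pct <= 100.0):
            raise ValidationError("collagen_fraction_pct must lie in [0, 100]")
        if self.rf_basal_cpm < 0 or self.rf_stim_cpm < 0:
            raise ValidationError("respiratory rates must be non-negative")

    @property
    def delta_rf_cpm(self) -> float:
        return self.rf_stim_cpm - self.rf_basal_cpm

    @property
    def lf_power_mmHg2(self) -> float:
        """Analytic LF band power of the systolic series (A^2 / 2)."""
        return self.lf_amp_mmHg ** 2 / 2.0

    @property
    def hf_power_bpm2(self) -> float:
        """Analytic HF band power of the heart-rate series (A^2 / 2)."""
        return self.hf_amp_bpm ** 2 / 2.0

    @property
    def lf_hf_target(self) -> float:
        return self.lf_power_mmHg2 / self.hf_power_bpm2


def amplitudes_for_ratio(lf_hf_ratio: float, hf_power: float) -> Tuple[float, float]:
    """Oscillation amplitudes giving the requested band powers.

    A sinusoid of amplitude A carries band power A^2/2, so
    ``hf_amp = sqrt(2 * hf_power)`` and
    ``lf_amp = sqrt(2 * ratio * hf_power)``.
    """
    if hf_power <= 0 or lf_hf_ratio < 0:
        raise ValidationError("hf_power must be > 0 and lf_hf_ratio >= 0")
    hf_amp = math.sqrt(2.0 * hf_power)
    lf_amp = math.sqrt(2.0 * lf_hf_ratio * hf_power)
    return lf_amp, hf_amp


def make_group_params(group_label: str, seed: int = 0) -> SubjectParams:
    """Return SubjectParams preset to a study arm's group means."""
    if group_label not in GROUP_STATS:
        raise ValidationError(
            f"unknown group label {group_label!r}; valid labels: {tuple(GROUP_STATS)}"
        )
    g = GROUP_STATS[group_label]
    lf_amp, hf_amp = amplitudes_for_ratio(g["lf_hf_ratio"][0], g["hf_power_bpm2"][0])
    return SubjectParams(
        group=group_label,
        hr_bpm=g["hr_bpm"][0],
        sbp_mmHg=g["sbp_mmHg"][0],
        dbp_mmHg=g["dbp_mmHg"][0],
        lf_amp_mmHg=lf_amp,
        hf_amp_bpm=hf_amp,
        brg_bpm_per_mmHg=g["brg_bpm_per_mmHg"][0],
        rf_basal_cpm=RF_BASAL_DEFAULT,
        rf_stim_cpm=RF_BASAL_DEFAULT + g["delta_rf_cpm"][0],
        collagen_fraction_pct=g["collagen_fraction_pct"][0],
        adrenaline_ng_ml=g["adrenaline_ng_ml"][0],
        noradrenaline_ng_ml=g["noradrenaline_ng_ml"][0],
        dopamine_ng_ml=g["dopamine_ng_ml"][0],
        seed=seed,
    )


# --------------------------------------------------------------------------
# Waveform synthesis primitives
# --------------------------------------------------------------------------

def _beat_times_and_hr(
    duration_s: float,
    rate_fn: Callable[[float], float],
    rng: np.random.Generator,
    hr_noise_sd: float,
) -> Tuple[np.ndarray, np.ndarray]:
    """Beat times whose derived beat-to-beat HR matches ``rate_fn``.

    The interval ending at beat i+1 satisfies
    ``60 / RR = rate_fn(t_{i+1}) + eps_i`` (fixed-point iteration), so the
    pipeline's HR series ``60000 / RR_ms`` timestamped at the later beat
    recovers the instantaneous target rate without sampling bias.
    """
    times = [0.0]
    hrs: List[float] = []
    t = 0.0
    while True:
        eps = rng.normal(0.0, hr_noise_sd) if hr_noise_sd > 0 else 0.0
        hr_next = max(rate_fn(t) + eps, 30.0)
        rr = 60.0 / hr_next
        for _ in range(6):
            hr_next = max(rate_fn(t + rr) + eps, 30.0)
            rr = 60.0 / hr_next
        t_next = t + rr
        if t_next > duration_s:
            break
        times.append(t_next)
        hrs.append(hr_next)
        t = t_next
    return np.asarray(times), np.asarray(hrs)


def _ecg_from_beats(
    beat_times: np.ndarray,
    duration_s: float,
    fs: float,
    rng: np.random.Generator,
    noise_sd: float,
    r_width_s: float = 0.008,
    r_amp_mV: float = 1.0,
) -> np.ndarray:
    n = int(round(duration_s * fs))
    x = np.zeros(n)
    half = int(math.ceil(5 * r_width_s * fs))
    for t in beat_times:
        c = t * fs
        i0 = max(0, int(c) - half)
        i1 = min(n, int(c) + half + 1)
        if i1 <= i0:
            continue
        idx = np.arange(i0, i1)
        x[idx] += r_amp_mV * np.exp(-0.5 * ((idx - c) / (r_width_s * fs)) ** 2)
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, n)
    return x


_PULSE_RISE_FRAC = 0.2      # fraction of the beat spent on the upstroke
_PULSE_DECAY_K = 1.0        # exponential decay constant of the downstroke


def _abp_from_beats(
    beat_times: np.ndarray,
    sbp_fn: Callable[[float], float],
    dbp_fn: Callable[[float], float],
    duration_s: float,
    fs: float,
    rng: np.random.Generator,
    level_noise_sd: float,
    wave_noise_sd: float,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pressure trace plus the per-beat systolic/diastolic truth."""
    n = int(round(duration_s * fs))
    x = np.empty(n)
    s_true = np.empty(max(len(beat_times) - 1, 0))
    d_true = np.empty_like(s_true)
    ek = math.exp(-_PULSE_DECAY_K)
    last = 0
    for i in range(len(beat_times) - 1):
        t0, t1 = beat_times[i], beat_times[i + 1]
        d = dbp_fn(t0) + (rng.normal(0.0, 0.5 * level_noise_sd) if level_noise_sd > 0 else 0.0)
        s = sbp_fn(t0) + (rng.normal(0.0, level_noise_sd) if level_noise_sd > 0 else 0.0)
        s = max(s, d + 5.0)
        s_true[i], d_true[i] = s, d
        i0 = int(math.ceil(t0 * fs))
        i1 = min(n, int(math.ceil(t1 * fs)))
        if i1 <= i0:
            continue
        tau = (np.arange(i0, i1) / fs - t0) / (t1 - t0)
        shape = np.empty(tau.size)
        rise = tau < _PULSE_RISE_FRAC
        shape[rise] = 0.5 * (1.0 - np.cos(np.pi * tau[rise] / _PULSE_RISE_FRAC))
        u = (tau[~rise] - _PULSE_RISE_FRAC) / (1.0 - _PULSE_RISE_FRAC)
        shape[~rise] = (np.exp(-_PULSE_DECAY_K * u) - ek) / (1.0 - ek)
        x[i0:i1] = d + (s - d) * shape
        last = i1
    # tail beyond the final complete beat: hold diastolic level
    x[last:] = d_true[-1] if s_true.size else dbp_fn(0.0)
    x[: int(math.ceil(beat_times[0] * fs))] = d_true[0] if s_true.size else dbp_fn(0.0)
    if wave_noise_sd > 0:
        x = x + rng.normal(0.0, wave_noise_sd, n)
    return x, s_true, d_true


def _tracheal_pressure(
    duration_s: float,
    fs: float,
    rf_cpm_fn: Callable[[np.ndarray], np.ndarray],
    rng: np.random.Generator,
    noise_sd: float,
    amp_cmH2O: float = 2.0,
    offset_cmH2O: float = 2.0,
) -> np.ndarray:
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    freq_hz = np.asarray(rf_cpm_fn(t), dtype=float) / 60.0
    phase = 2.0 * np.pi * np.cumsum(freq_hz) / fs
    x = offset_cmH2O + amp_cmH2O * np.sin(phase)
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, n)
    return x


def _base_ground_truth(params: SubjectParams, beat_times, hrs, s_true, d_true) -> Dict:
    return {
        "params": params,
        "beat_times": beat_times,
        "hr_times": beat_times[1:],
        "hr_values": hrs,
        "sbp_times": beat_times[:-1],
        "sbp_values": s_true,
        "dbp_values": d_true,
    }


# --------------------------------------------------------------------------
# Recording simulators
# --------------------------------------------------------------------------

def simulate_baseline_recording(
    params: SubjectParams,
    duration_s: float = 180.0,
    sampling_rate: float = 1000.0,
    seed: Optional[int] = None,
) -> RecordingBundle:
    """Simulate a resting multichannel recording (>= one 180-s window)."""
    if duration_s < 180.0:
        raise ValidationError("duration_s must cover one 180-s analysis window")
    if sampling_rate < 100.0:
        raise ValidationError("sampling_rate must be >= 100 Hz")
    if params.lf_amp_mmHg > 0 and duration_s < 10.0 / params.lf_freq_Hz:
        warnings.warn(
            "recording shorter than 10 LF cycles; spectral resolution will suffer",
            stacklevel=2,
        )
    rng = np.random.default_rng(params.seed if seed is None else seed)

    two_pi = 2.0 * np.pi
    rate_fn = lambda t: params.hr_bpm + params.hf_amp_bpm * math.sin(
        two_pi * params.hf_freq_Hz * t
    )
    sbp_fn = lambda t: params.sbp_mmHg + params.lf_amp_mmHg * math.sin(
        two_pi * params.lf_freq_Hz * t
    )
    dbp_fn = lambda t: params.dbp_mmHg

    beat_times, hrs = _beat_times_and_hr(duration_s, rate_fn, rng, params.noise.hr_bpm)
    ecg = _ecg_from_beats(beat_times, duration_s, sampling_rate, rng, params.noise.ecg_mV)
    abp, s_true, d_true = _abp_from_beats(
        beat_times, sbp_fn, dbp_fn, duration_s, sampling_rate, rng,
        params.noise.bp_level_mmHg, params.noise.bp_wave_mmHg,
    )
    trach = _tracheal_pressure(
        duration_s, sampling_rate,
        lambda t: np.full_like(t, params.rf_basal_cpm),
        rng, params.noise.tracheal_cmH2O,
    )

    channels = {
        "ecg": Waveform("ecg", ecg, sampling_rate, units="mV"),
        "abp": Waveform("abp", abp, sampling_rate, units="mmHg"),
        "tracheal": Waveform("tracheal", trach, sampling_rate, units="cmH2O"),
    }
    gt = _base_ground_truth(params, beat_times, hrs, s_true, d_true)
    gt["rf_cpm"] = params.rf_basal_cpm
    return RecordingBundle(
        channels,
        events=[],
        metadata={"group": params.group, "kind": "baseline"},
        ground_truth=gt,
    )


def simulate_phenylephrine_response(
    params: SubjectParams,
    ramp_mmHg: float = 40.0,
    ramp_s: float = 60.0,
    seed: Optional[int] = None,
    sampling_rate: float = 1000.0,
    baseline_s: float = 60.0,
    post_s: float = 30.0,
) -> RecordingBundle:
    """Simulate a phenylephrine bolus: BP ramps up, HR falls reflexively.

    Blood pressure rises linearly by ``ramp_mmHg`` over ``ramp_s`` after
    the injection event; the instantaneous heart rate falls by
    ``brg_bpm_per_mmHg * delta_BP(t)``.
    """
    if ramp_mmHg <= 0:
        raise ValidationError("ramp_mmHg must be > 0")
    if baseline_s < 60.0:
        raise ValidationError("at least 60 s of pre-injection baseline is required")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    duration_s = baseline_s + ramp_s + post_s
    t_inj = baseline_s
    two_pi = 2.0 * np.pi

    def delta_bp(t: float) -> float:
        return ramp_mmHg * min(max((t - t_inj) / ramp_s, 0.0), 1.0)

    rate_fn = lambda t: (
        params.hr_bpm
        + params.hf_amp_bpm * math.sin(two_pi * params.hf_freq_Hz * t)
        - params.brg_bpm_per_mmHg * delta_bp(t)
    )
    sbp_fn = lambda t: (
        params.sbp_mmHg
        + params.lf_amp_mmHg * math.sin(two_pi * params.lf_freq_Hz * t)
        + delta_bp(t)
    )
    dbp_fn = lambda t: params.dbp_mmHg + delta_bp(t)

    beat_times, hrs = _beat_times_and_hr(duration_s, rate_fn, rng, params.noise.hr_bpm)
    ecg = _ecg_from_beats(beat_times, duration_s, sampling_rate, rng, params.noise.ecg_mV)
    abp, s_true, d_true = _abp_from_beats(
        beat_times, sbp_fn, dbp_fn, duration_s, sampling_rate, rng,
        params.noise.bp_level_mmHg, params.noise.bp_wave_mmHg,
    )
    trach = _tracheal_pressure(
        duration_s, sampling_rate,
        lambda t: np.full_like(t, params.rf_basal_cpm),
        rng, params.noise.tracheal_cmH2O,
    )
    channels = {
        "ecg": Waveform("ecg", ecg, sampling_rate, units="mV"),
        "abp": Waveform("abp", abp, sampling_rate, units="mmHg"),
        "tracheal": Waveform("tracheal", trach, sampling_rate, units="cmH2O"),
    }
    gt = _base_ground_truth(params, beat_times, hrs, s_true, d_true)
    gt.update(
        injection_time_s=t_inj,
        ramp_mmHg=ramp_mmHg,
        ramp_s=ramp_s,
        programmed_gain=params.brg_bpm_per_mmHg,
    )
    return RecordingBundle(
        channels,
        events=[Event("phenylephrine", t_inj)],
        metadata={"group": params.group, "kind": "phenylephrine"},
        ground_truth=gt,
    )


def simulate_lobeline_response(
    params: SubjectParams,
    seed: Optional[int] = None,
    sampling_rate: float = 1000.0,
    baseline_s: float = 60.0,
    response_s: float = 60.0,
) -> RecordingBundle:
    """Simulate a lobeline bolus: respiratory rate steps up at injection."""
    if params.rf_stim_cpm < 0:
        raise ValidationError("rf_stim_cpm must be >= 0")
    if baseline_s < 30.0 or response_s < 30.0:
        raise ValidationError("baseline and response segments must each cover >= 30 s")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    duration_s = baseline_s + response_s
    t_inj = baseline_s
    two_pi = 2.0 * np.pi

    rate_fn = lambda t: params.hr_bpm + params.hf_amp_bpm * math.sin(
        two_pi * params.hf_freq_Hz * t
    )
    sbp_fn = lambda t: params.sbp_mmHg + params.lf_amp_mmHg * math.sin(
        two_pi * params.lf_freq_Hz * t
    )
    beat_times, hrs = _beat_times_and_hr(duration_s, rate_fn, rng, params.noise.hr_bpm)
    ecg = _ecg_from_beats(beat_times, duration_s, sampling_rate, rng, params.noise.ecg_mV)
    abp, s_true, d_true = _abp_from_beats(
        beat_times, sbp_fn, lambda t: params.dbp_mmHg, duration_s, sampling_rate, rng,
        params.noise.bp_level_mmHg, params.noise.bp_wave_mmHg,
    )
    trach = _tracheal_pressure(
        duration_s, sampling_rate,
        lambda t: np.where(t < t_inj, params.rf_basal_cpm, params.rf_stim_cpm),
        rng, params.noise.tracheal_cmH2O,
    )
    channels = {
        "ecg": Waveform("ecg", ecg, sampling_rate, units="mV"),
        "abp": Waveform("abp", abp, sampling_rate, units="mmHg"),
        "tracheal": Waveform("tracheal", trach, sampling_rate, units="cmH2O"),
    }
    gt = _base_ground_truth(params, beat_times, hrs, s_true, d_true)
    gt.update(
        injection_time_s=t_inj,
        rf_basal_cpm=params.rf_basal_cpm,
        rf_stim_cpm=params.rf_stim_cpm,
        programmed_delta_rf=params.delta_rf_cpm,
    )
    return RecordingBundle(
        channels,
        events=[Event("lobeline", t_inj)],
        metadata={"group": params.group, "kind": "lobeline"},
        ground_truth=gt,
    )


# --------------------------------------------------------------------------
# Histology image generator
# --------------------------------------------------------------------------

_COLLAGEN_RGB = np.array([170.0, 38.0, 48.0])      # picrosirius-like red
_MYOCARDIUM_RGB = np.array([205.0, 185.0, 95.0])   # yellow-green cytoplasm
_BACKGROUND_RGB = np.array([246.0, 246.0, 246.0])  # near-white slide


def simulate_histology_image(
    collagen_fraction_pct: float,
    width: int = 512,
    height: int = 512,
    seed: int = 0,
    blob_sigma: float = 8.0,
) -> Tuple[np.ndarray, Dict[str, np.ndarray]]:
    """Synthesize a picrosirius-like RGB section with exact collagen count.

    Returns ``(image, truth)`` where ``truth['tissue_mask']`` and
    ``truth['collagen_mask']`` are boolean arrays; the collagen mask has
    exactly ``floor(fraction * tissue_px / 100)`` pixels, spatially
    clustered by ranking a smoothed random field.
    """
    if not (0.0 <= collagen_fraction_pct <= 100.0):
        raise ValidationError("collagen_fraction_pct must lie in [0, 100]")
    if width < 16 or height < 16:
        raise ValidationError("image must be at least 16 x 16")
    rng = np.random.default_rng(seed)

    yy, xx = np.mgrid[0:height, 0:width]
    cy, cx = height / 2.0, width / 2.0
    wobble = ndimage.gaussian_filter(rng.standard_normal((height, width)),
                                     max(height, width) / 12.0)
    wobble = wobble / max(np.std(wobble), 1e-12)
    r2 = ((yy - cy) / (0.40 * height)) ** 2 + ((xx - cx) / (0.42 * width)) ** 2
    tissue = (r2 + 0.18 * wobble) < 1.0

    tissue_px = int(tissue.sum())
    if tissue_px == 0:
        raise ValidationError("degenerate tissue mask (empty)")
    n_collagen = int(math.floor(collagen_fraction_pct * tissue_px / 100.0))

    field_img = ndimage.gaussian_filter(rng.standard_normal((height, width)), blob_sigma)
    order = np.argsort(field_img[tissue], kind="stable")[::-1]
    collagen = np.zeros((height, width), dtype=bool)
    tissue_idx = np.flatnonzero(tissue.ravel())
    collagen.ravel()[tissue_idx[order[:n_collagen]]] = True

    img = np.empty((height, width, 3))
    img[:] = _BACKGROUND_RGB + rng.normal(0.0, 2.0, (height, width, 3))
    myo = tissue & ~collagen
    img[myo] = _MYOCARDIUM_RGB + rng.normal(0.0, 7.0, (int(myo.sum()), 3))
    img[collagen] = _COLLAGEN_RGB + rng.normal(0.0, 6.0, (n_collagen, 3))
    img = np.clip(img, 0, 255).astype(np.uint8)

    truth = {
        "tissue_mask": tissue,
        "collagen_mask": collagen,
        "fraction_pct": 100.0 * n_collagen / tissue_px,
    }
    return img, truth


# --------------------------------------------------------------------------
# Cohort generation
# --------------------------------------------------------------------------

@dataclass
class GroupDesign:
    """Between-subject distributions for a full cohort.

    ``stats[group][variable] = (mean, sd)`` where the default SD is
    reconstructed from the printed SEM as ``SEM * sqrt(n)``.
    """

    sizes: Dict[str, int]
    stats: Dict[str, Dict[str, Tuple[float, float]]]

    def __post_init__(self):
        for group, n in self.sizes.items():
            if group not in self.stats:
                raise ValidationError(f"no distribution stats for group {group!r}")
            if n < 1:
                raise ValidationError("group sizes must be >= 1")
            for var, (mean, sd) in self.stats[group].items():
                if sd < 0:
                    warnings.warn(
                        f"negative SD for {group}.{var}; falling back to 0", stacklevel=2
                    )
                    self.stats[group][var] = (mean, 0.0)


def default_design(sd_scale: float = 1.0) -> GroupDesign:
    """The study's design: printed means, SD = SEM * sqrt(n)."""
    stats = {
        group: {
            var: (mean, sem * math.sqrt(GROUP_SIZES[group]) * sd_scale)
            for var, (mean, sem) in variables.items()
        }
        for group, variables in GROUP_STATS.items()
    }
    return GroupDesign(sizes=dict(GROUP_SIZES), stats=stats)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float,
    lo: float = -math.inf, hi: float = math.inf, max_tries: int = 1000,
) -> float:
    if sd == 0:
        return float(min(max(mean, lo), hi))
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    warnings.warn(
        f"truncated-normal rejection failed for mean={mean}, sd={sd}; clipping",
        stacklevel=2,
    )
    return float(min(max(mean, lo), hi))


def draw_subject_params(
    group: str,
    stats: Dict[str, Tuple[float, float]],
    seed: int,
    noise: Optional[NoiseLevels] = None,
) -> SubjectParams:
    """Draw one subject from a group's between-subject distributions."""
    rng = np.random.default_rng(seed)
    g = lambda var: stats[var]
    sbp = _truncated_normal(rng, *g("sbp_mmHg"), lo=40.0)
    dbp = _truncated_normal(rng, *g("dbp_mmHg"), lo=20.0, hi=sbp - 10.0)
    hr = _truncated_normal(rng, *g("hr_bpm"), lo=60.0, hi=700.0)
    brg = _truncated_normal(rng, *g("brg_bpm_per_mmHg"), lo=0.0)
    delta_rf = _truncated_normal(rng, *g("delta_rf_cpm"), lo=5.0 - RF_BASAL_DEFAULT)
    ratio = _truncated_normal(rng, *g("lf_hf_ratio"), lo=0.01)
    hf_power = _truncated_normal(rng, *g("hf_power_bpm2"), lo=0.05)
    collagen = _truncated_normal(rng, *g("collagen_fraction_pct"), lo=0.0, hi=100.0)
    adr = _truncated_normal(rng, *g("adrenaline_ng_ml"), lo=0.0)
    nor = _truncated_normal(rng, *g("noradrenaline_ng_ml"), lo=0.0)
    dop = _truncated_normal(rng, *g("dopamine_ng_ml"), lo=0.0)
    lf_amp, hf_amp = amplitudes_for_ratio(ratio, hf_power)
    return SubjectParams(
        group=group,
        hr_bpm=hr, sbp_mmHg=sbp, dbp_mmHg=dbp,
        lf_amp_mmHg=lf_amp, hf_amp_bpm=hf_amp,
        brg_bpm_per_mmHg=brg,
        rf_basal_cpm=RF_BASAL_DEFAULT,
        rf_stim_cpm=RF_BASAL_DEFAULT + delta_rf,
        collagen_fraction_pct=collagen,
        adrenaline_ng_ml=adr, noradrenaline_ng_ml=nor, dopamine_ng_ml=dop,
        noise=noise if noise is not None else NoiseLevels(),
        seed=seed,
    )


# fixed, large, coprime-ish seed offsets per recording kind so that one
# subject's streams never reuse a neighbouring subject's seed
_SEED_BASELINE = 0
_SEED_PHENYLEPHRINE = 10_000_019
_SEED_LOBELINE = 20_000_003
_SEED_HISTOLOGY = 30_000_001


@dataclass
class SyntheticSubject:
    """One cohort member; recordings are generated on demand."""

    subject_id: str
    group: str
    params: SubjectParams

    def baseline(self, duration_s: float = 180.0, sampling_rate: float = 1000.0):
        return simulate_baseline_recording(
            self.params, duration_s, sampling_rate,
            seed=self.params.seed + _SEED_BASELINE,
        )

    def phenylephrine(self, ramp_mmHg: float = 40.0, ramp_s: float = 60.0,
                      sampling_rate: float = 1000.0):
        return simulate_phenylephrine_response(
            self.params, ramp_mmHg, ramp_s,
            seed=self.params.seed + _SEED_PHENYLEPHRINE,
            sampling_rate=sampling_rate,
        )

    def lobeline(self, sampling_rate: float = 1000.0):
        return simulate_lobeline_response(
            self.params, seed=self.params.seed + _SEED_LOBELINE,
            sampling_rate=sampling_rate,
        )

    def histology(self, width: int = 512, height: int = 512):
        return simulate_histology_image(
            self.params.collagen_fraction_pct, width, height,
            seed=self.params.seed + _SEED_HISTOLOGY,
        )


@dataclass
class Cohort:
    seed: int
    design: GroupDesign
    subjects: List[SyntheticSubject]

    def by_group(self) -> Dict[str, List[SyntheticSubject]]:
        out: Dict[str, List[SyntheticSubject]] = {g: [] for g in self.design.sizes}
        for s in self.subjects:
            out[s.group].append(s)
        return out


def simulate_cohort(
    design: Optional[GroupDesign] = None,
    seed: int = 0,
    noise: Optional[NoiseLevels] = None,
) -> Cohort:
    """Draw a full cohort; subject i uses seed ``seed + i``."""
    design = design if design is not None else default_design()
    subjects: List[SyntheticSubject] = []
    index = 0
    for group in design.sizes:
        for k in range(design.sizes[group]):
            params = draw_subject_params(
                group, design.stats[group], seed=seed + index, noise=noise,
            )
            subjects.append(
                SyntheticSubject(subject_id=f"{group}-{k + 1:02d}", group=group,
                                 params=params)
            )
            index += 1
    return Cohort(seed=seed, design=design, subjects=subjects)


def catecholamine_table(cohort: Cohort) -> "pd.DataFrame":
    """Long-format table of per-subject urinary catecholamines."""
    import pandas as pd

    rows = []
    for s in cohort.subjects:
        for var, value in (
            ("adrenaline", s.params.adrenaline_ng_ml),
            ("noradrenaline", s.params.noradrenaline_ng_ml),
            ("dopamine", s.params.dopamine_ng_ml),
        ):
            rows.append(dict(subject=s.subject_id, group=s.group, variable=var,
                             value=value, units="ng/mL"))
    return pd.DataFrame(rows)
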
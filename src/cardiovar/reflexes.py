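"""Provoked autonomic reflex quantification.

Baroreflex gain is the peak change in mean arterial pressure after a
phenylephrine bolus divided into the accompanying heart-rate change:
``gain = |delta_HR| / delta_BP`` in bpm/mmHg.  Chemoreflex sensitivity
is the respiratory-rate change after a lobeline bolus:
``delta_RF = RF_stim - RF_basal`` in cycles/min.

Window convention (the source protocol gives only the formulas): the
baseline is the 30 s immediately preceding the injection, the response
window the 60 s after it.  A regression-slope estimator over the rising
phase is available as an alternative for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import stats as sstats

from .core import BeatSeries, ProvocationError, RecordingBundle, ValidationError

#: minimum pressure rise for a phenylephrine trial to count as provoked
MIN_DELTA_BP_MMHG = 2.0


@dataclass
class ReflexWindow:
    """Baseline/response intervals around one injection."""

    baseline: Tuple[float, float]
    response: Tuple[float, float]
    stimulus: str
    injection_time_s: float

    def __post_init__(self):
        if self.stimulus not in ("phenylephrine", "lobeline"):
            raise ValidationError("stimulus must be 'phenylephrine' or 'lobeline'")
        b0, b1 = self.baseline
        r0, r1 = self.response
        if not (b0 < b1 and r0 < r1):
            raise ValidationError("baseline and response windows must be non-empty")
        if b1 > self.injection_time_s + 1e-9:
            raise ValidationError("baseline must end at or before the injection")
        if r0 < self.injection_time_s - 1e-9:
            raise ValidationError("response must start at the injection")


def window_from_events(
    bundle: RecordingBundle,
    stimulus: str,
    baseline_s: float = 30.0,
    response_s: float = 60.0,
) -> ReflexWindow:
    """Build the default reflex window around a bundle's injection event."""
    t_inj = bundle.event_time(stimulus)
    return ReflexWindow(
        baseline=(max(0.0, t_inj - baseline_s), t_inj),
        response=(t_inj, t_inj + response_s),
        stimulus=stimulus,
        injection_time_s=t_inj,
    )


@dataclass
class BaroreflexResult:
    delta_bp: float                 # mmHg, peak response minus baseline mean
    delta_hr: float                 # bpm, signed (negative = bradycardia)
    gain: float                     # |delta_hr| / delta_bp, bpm/mmHg
    peak_time_s: float


@dataclass
class ChemoreflexResult:
    rf_basal: float                 # cpm
    rf_stim: float                  # cpm
    delta_rf: float                 # cpm, signed


def _window_mean(series: BeatSeries, t0: float, t1: float, what: str) -> float:
    seg = series.slice(t0, t1)
    if len(seg) == 0:
        raise ValidationError(f"no {what} beats inside window [{t0}, {t1}) s")
    return float(np.mean(seg.values))


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1 or x.size < width:
        return x
    kernel = np.ones(width) / width
    # reflect the edges so the smoothed series keeps its length and level
    padded = np.concatenate([x[width - 1:0:-1], x, x[-2:-width - 1:-1]])
    return np.convolve(padded, kernel, mode="same")[width - 1: width - 1 + x.size]


def baroreflex_gain(
    mbp: BeatSeries,
    hr: BeatSeries,
    window: ReflexWindow,
    smooth_beats: int = 5,
    hr_halfwidth_s: float = 2.0,
) -> BaroreflexResult:
    """Peak-delta baroreflex gain from mean-pressure and HR beat series."""
    if window.stimulus != "phenylephrine":
        raise ValidationError("baroreflex_gain requires a phenylephrine window")
    b0, b1 = window.baseline
    r0, r1 = window.response
    base_bp = _window_mean(mbp, b0, b1, "pressure")
    base_hr = _window_mean(hr, b0, b1, "heart-rate")

    resp = mbp.slice(r0, r1)
    if len(resp) < smooth_beats:
        raise ValidationError("too few beats in the response window")
    smoothed = _moving_average(resp.values, smooth_beats)
    peak_idx = int(np.argmax(smoothed))
    peak_time = float(resp.times[peak_idx])
    delta_bp = float(smoothed[peak_idx] - base_bp)
    if delta_bp <= MIN_DELTA_BP_MMHG:
        raise ProvocationError(
            f"pressure rose only {delta_bp:.2f} mmHg (<= {MIN_DELTA_BP_MMHG}); "
            "failed phenylephrine provocation"
        )
    hr_at_peak = _window_mean(
        hr, peak_time - hr_halfwidth_s, peak_time + hr_halfwidth_s, "heart-rate"
    )
    delta_hr = float(hr_at_peak - base_hr)
    return BaroreflexResult(
        delta_bp=delta_bp,
        delta_hr=delta_hr,
        gain=abs(delta_hr) / delta_bp,
        peak_time_s=peak_time,
    )


def baroreflex_gain_regression(
    mbp: BeatSeries,
    hr: BeatSeries,
    window: ReflexWindow,
) -> BaroreflexResult:
    """Alternative estimator: HR-vs-BP regression slope over the response.

    HR beats are matched to the nearest pressure beat; the gain is the
    absolute slope of the least-squares line.
    """
    if window.stimulus != "phenylephrine":
        raise ValidationError("baroreflex_gain requires a phenylephrine window")
    r0, r1 = window.response
    bp_seg = mbp.slice(r0, r1)
    hr_seg = hr.slice(r0, r1)
    if len(bp_seg) < 3 or len(hr_seg) < 3:
        raise ValidationError("too few beats in the response window")
    hr_on_bp = np.interp(bp_seg.times, hr_seg.times, hr_seg.values)
    if np.ptp(bp_seg.values) <= MIN_DELTA_BP_MMHG:
        raise ProvocationError("pressure span too small for regression gain")
    fit = sstats.linregress(bp_seg.values, hr_on_bp)
    base_bp = _window_mean(mbp, *window.baseline, "pressure")
    base_hr = _window_mean(hr, *window.baseline, "heart-rate")
    delta_bp = float(np.max(bp_seg.values) - base_bp)
    return BaroreflexResult(
        delta_bp=delta_bp,
        delta_hr=float(fit.slope * delta_bp),
        gain=abs(float(fit.slope)),
        peak_time_s=float(bp_seg.times[int(np.argmax(bp_seg.values))]),
    )


def chemoreflex_delta(rf: BeatSeries, window: ReflexWindow) -> ChemoreflexResult:
    """Respiratory-rate change: max windowed RF after minus baseline mean."""
    if window.stimulus != "lobeline":
        raise ValidationError("chemoreflex_delta requires a lobeline window")
    good = rf if rf.quality is None else BeatSeries(
        rf.times[rf.quality], rf.values[rf.quality], kind=rf.kind, units=rf.units
    )
    basal = good.slice(*window.baseline)
    resp = good.slice(*window.response)
    if len(basal) == 0:
        raise ValidationError("no reliable RF estimates in the baseline window")
    if len(resp) == 0:
        raise ValidationError(
            "response window shorter than one RF analysis window (no estimates)"
        )
    rf_basal = float(np.mean(basal.values))
    rf_stim = float(np.max(resp.values))
    return ChemoreflexResult(rf_basal=rf_basal, rf_stim=rf_stim,
                             delta_rf=rf_stim - rf_basal)
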
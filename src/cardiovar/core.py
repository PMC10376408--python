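"""Core domain types shared by every pipeline stage.

The pipeline works on two basic representations of a physiological
recording:

``Waveform``
    A uniformly sampled channel (ECG in mV, arterial pressure in mmHg,
    tracheal pressure in cmH2O).  The time base is implicit: sample ``i``
    sits at ``start_time + i / sampling_rate``.

``BeatSeries``
    An event-indexed series (beat times plus one value per beat), in
    general unevenly spaced.  RR intervals, beat-to-beat heart rate and
    per-beat pressure levels are all ``BeatSeries``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

#: The four study arms, in dose order.
STUDY_GROUPS = ("CTL", "DOX8", "DOX16", "DOX20")


class PipelineError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(PipelineError, ValueError):
    """A precondition on inputs or parameters was violated."""


class FormatError(PipelineError):
    """A file does not conform to the expected external format."""


class ParseError(FormatError):
    """A cell/record could not be parsed; carries the offending row."""

    def __init__(self, message: str, row: Optional[int] = None):
        super().__init__(message)
        self.row = row


class ProvocationError(PipelineError):
    """A pharmacological provocation trial failed (e.g. flat BP response)."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class Event:
    """A labelled instant in a recording (injections, window boundaries)."""

    label: str
    time: float


@dataclass
class Waveform:
    """A uniformly sampled physiological channel."""

    channel_name: str
    samples: np.ndarray
    sampling_rate: float
    start_time: float = 0.0
    units: str = ""

    def __post_init__(self):
        self.samples = _as_float_array(self.samples, "samples")
        if not self.sampling_rate > 0:
            raise ValidationError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.samples.size < 2:
            raise ValidationError("a Waveform needs at least 2 samples")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Length of the covered interval in seconds (n / rate)."""
        return self.samples.size / self.sampling_rate

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.sampling_rate

    def require_finite(self) -> "Waveform":
        if not np.all(np.isfinite(self.samples)):
            bad = int(np.flatnonzero(~np.isfinite(self.samples))[0])
            raise ValidationError(
                f"channel {self.channel_name!r} contains a non-finite sample at index {bad}"
            )
        return self

    def segment(self, t0: float, t1: float) -> "Waveform":
        """Return the sub-waveform covering [t0, t1)."""
        if t1 <= t0:
            raise ValidationError("segment requires t1 > t0")
        i0 = max(0, int(np.ceil((t0 - self.start_time) * self.sampling_rate)))
        i1 = min(self.samples.size, int(np.ceil((t1 - self.start_time) * self.sampling_rate)))
        if i1 - i0 < 2:
            raise ValidationError(f"segment [{t0}, {t1}) contains fewer than 2 samples")
        return Waveform(
            self.channel_name,
            self.samples[i0:i1].copy(),
            self.sampling_rate,
            start_time=self.start_time + i0 / self.sampling_rate,
            units=self.units,
        )


@dataclass
class RecordingBundle:
    """All channels of one acute experiment plus its event markers.

    ``ground_truth`` is populated by the synthetic generator (beat times,
    per-beat values, generator parameters) and is never consumed by
    analysis code -- it exists purely so tests can score recovery.
    """

    channels: Dict[str, Waveform]
    events: List[Event] = field(default_factory=list)
    metadata: Dict[str, object] = field(default_factory=dict)
    ground_truth: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self):
        if not self.channels:
            raise ValidationError("a RecordingBundle needs at least one channel")
        group = self.metadata.get("group")
        if group is not None and group not in STUDY_GROUPS:
            raise ValidationError(
                f"unknown group label {group!r}; expected one of {STUDY_GROUPS}"
            )
        t0 = min(w.start_time for w in self.channels.values())
        t1 = max(w.end_time for w in self.channels.values())
        for ev in self.events:
            if not (t0 <= ev.time <= t1):
                raise ValidationError(
                    f"event {ev.label!r} at t={ev.time} s lies outside the recording "
                    f"span [{t0}, {t1}] s"
                )

    def channel(self, name: str) -> Waveform:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"no channel {name!r}; available: {sorted(self.channels)}"
            ) from None

    def event_time(self, label: str) -> float:
        for ev in self.events:
            if ev.label == label:
                return ev.time
        raise KeyError(f"no event labelled {label!r}; have {[e.label for e in self.events]}")


@dataclass
class BeatSeries:
    """Event-indexed series: strictly increasing times, one value each.

    ``quality`` is an optional boolean mask (True = reliable) used by
    windowed estimators such as respiratory frequency.
    """

    times: np.ndarray
    values: np.ndarray
    kind: str = ""
    units: str = ""
    quality: Optional[np.ndarray] = None

    def __post_init__(self):
        self.times = _as_float_array(self.times, "times")
        self.values = _as_float_array(self.values, "values")
        if self.times.size != self.values.size:
            raise ValidationError(
                f"times ({self.times.size}) and values ({self.values.size}) differ in length"
            )
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValidationError("beat times must be strictly increasing")
        if self.quality is not None:
            self.quality = np.asarray(self.quality, dtype=bool)
            if self.quality.size != self.times.size:
                raise ValidationError("quality mask length mismatch")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def span(self) -> float:
        if len(self) < 2:
            return 0.0
        return float(self.times[-1] - self.times[0])

    def slice(self, t0: float, t1: float) -> "BeatSeries":
        """Beats with time in [t0, t1)."""
        mask = (self.times >= t0) & (self.times < t1)
        return BeatSeries(
            self.times[mask],
            self.values[mask],
            kind=self.kind,
            units=self.units,
            quality=None if self.quality is None else self.quality[mask],
        )


@dataclass
class PressureBeats:
    """Per-beat systolic / diastolic / mean arterial pressure."""

    times: np.ndarray
    sbp: np.ndarray
    dbp: np.ndarray
    mbp: np.ndarray

    def __post_init__(self):
        self.times = _as_float_array(self.times, "times")
        self.sbp = _as_float_array(self.sbp, "sbp")
        self.dbp = _as_float_array(self.dbp, "dbp")
        self.mbp = _as_float_array(self.mbp, "mbp")
        n = self.times.size
        if not (self.sbp.size == self.dbp.size == self.mbp.size == n):
            raise ValidationError("PressureBeats arrays must share one length")
        # allow a hair of numerical slack from time-averaging
        tol = 1e-9
        if np.any(self.sbp < self.mbp - tol) or np.any(self.mbp < self.dbp - tol):
            raise ValidationError("pressure ordering sBP >= mBP >= dBP violated")

    def __len__(self) -> int:
        return int(self.times.size)

    def series(self, which: str) -> BeatSeries:
        """Return one component ('sbp' | 'dbp' | 'mbp') as a BeatSeries."""
        if which not in ("sbp", "dbp", "mbp"):
            raise ValidationError("which must be 'sbp', 'dbp' or 'mbp'")
        return BeatSeries(self.times, getattr(self, which), kind=which.upper(), units="mmHg")
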
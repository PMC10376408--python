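"""Minimal EDF (European Data Format) reader/writer.

Implements the plain-EDF subset the pipeline needs: an arbitrary number
of signals, 16-bit little-endian samples, per-signal physical scaling.
The writer stores the whole recording as a single data record whose
duration equals the recording length, which keeps sample counts exact
for non-integer sampling rates; the reader accepts any record layout.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np

from .core import FormatError, Waveform

_HDR_FIXED = 256
_HDR_PER_SIGNAL = 256


def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise FormatError(f"EDF header field {s!r} exceeds {width} ASCII characters")
    return s.ljust(width).encode("ascii")


def _fmt_float(x: float, width: int = 8) -> bytes:
    for fmt in (f"%.{width - 2}g", "%.5g", "%.4g", "%.3g"):
        s = fmt % x
        if len(s) <= width:
            return s.ljust(width).encode("ascii")
    raise FormatError(f"cannot format {x} into {width} EDF characters")


def _header_bounds(data_min: float, data_max: float) -> tuple:
    """Physical min/max that survive the 8-char ASCII header round trip.

    The writer must quantize against the *header* values (what a reader
    will see), so the exact data range is widened until its formatted
    representation still covers the data.
    """
    if data_max == data_min:                      # EDF forbids a zero span
        data_max = data_min + 1.0
    span = data_max - data_min
    for k in range(1, 20):
        margin = span * 1e-4 * k
        lo = float(_fmt_float(data_min - margin).decode("ascii"))
        hi = float(_fmt_float(data_max + margin).decode("ascii"))
        if lo <= data_min and hi >= data_max and hi > lo:
            return lo, hi
    raise FormatError(f"cannot encode physical range [{data_min}, {data_max}]")


@dataclass
class _SignalHeader:
    label: str
    units: str
    phys_min: float
    phys_max: float
    dig_min: int
    dig_max: int
    n_per_record: int


def write_edf(waveforms: Sequence[Waveform], path: str | os.PathLike) -> None:
    """Write waveforms to ``path`` as a single-record EDF file."""
    if not waveforms:
        raise FormatError("write_edf needs at least one waveform")
    duration = waveforms[0].duration
    for w in waveforms:
        if not math.isclose(w.duration, duration, rel_tol=1e-9):
            raise FormatError("all channels in one EDF file must share a duration")
        w.require_finite()

    ns = len(waveforms)
    header = bytearray()
    header += _ascii("0", 8)                      # version
    header += _ascii("X X X X", 80)               # patient id (anonymous)
    header += _ascii("Startdate X X X X", 80)     # recording id
    header += _ascii("01.01.00", 8)               # start date
    header += _ascii("00.00.00", 8)               # start time
    header += _ascii(_HDR_FIXED + _HDR_PER_SIGNAL * ns, 8)
    header += _ascii("", 44)                      # reserved
    header += _ascii(1, 8)                        # number of data records
    header += _fmt_float(duration, 8)             # record duration, seconds
    header += _ascii(ns, 4)

    sig_headers: List[_SignalHeader] = []
    for w in waveforms:
        pmin, pmax = _header_bounds(float(np.min(w.samples)), float(np.max(w.samples)))
        sig_headers.append(
            _SignalHeader(w.channel_name, w.units, pmin, pmax, -32768, 32767, w.n_samples)
        )

    # Per-signal header area: each field is written for all signals in turn.
    for h in sig_headers:
        header += _ascii(h.label, 16)
    for h in sig_headers:
        header += _ascii("", 80)                  # transducer
    for h in sig_headers:
        header += _ascii(h.units, 8)
    for h in sig_headers:
        header += _fmt_float(h.phys_min, 8)
    for h in sig_headers:
        header += _fmt_float(h.phys_max, 8)
    for h in sig_headers:
        header += _ascii(h.dig_min, 8)
    for h in sig_headers:
        header += _ascii(h.dig_max, 8)
    for h in sig_headers:
        header += _ascii("", 80)                  # prefiltering
    for h in sig_headers:
        header += _ascii(h.n_per_record, 8)
    for h in sig_headers:
        header += _ascii("", 32)                  # reserved

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for w, h in zip(waveforms, sig_headers):
            scale = (h.phys_max - h.phys_min) / (h.dig_max - h.dig_min)
            dig = np.round((w.samples - h.phys_min) / scale) + h.dig_min
            fh.write(dig.astype("<i2").tobytes())


def _read_exact(fh, n: int, what: str) -> bytes:
    data = fh.read(n)
    if len(data) != n:
        raise FormatError(f"truncated EDF file while reading {what}")
    return data


def read_edf(path: str | os.PathLike) -> Dict[str, Waveform]:
    """Read every signal of an EDF file into Waveforms keyed by label."""
    with open(path, "rb") as fh:
        fixed = _read_exact(fh, _HDR_FIXED, "fixed header")
        try:
            n_records = int(fixed[236:244].decode("ascii").strip())
            rec_duration = float(fixed[244:252].decode("ascii").strip())
            ns = int(fixed[252:256].decode("ascii").strip())
        except (UnicodeDecodeError, ValueError) as exc:
            raise FormatError(f"corrupt EDF header in {path}: {exc}") from None
        if ns <= 0 or n_records <= 0 or rec_duration <= 0:
            raise FormatError(f"corrupt EDF header in {path} (ns={ns}, records={n_records})")

        sig = _read_exact(fh, _HDR_PER_SIGNAL * ns, "signal headers")

        def fields(offset: int, width: int) -> List[str]:
            base = offset * ns
            return [
                sig[base + i * width: base + (i + 1) * width].decode("ascii").strip()
                for i in range(ns)
            ]

        labels = fields(0, 16)
        units = fields(16 + 80, 8)
        try:
            phys_min = [float(v) for v in fields(16 + 80 + 8, 8)]
            phys_max = [float(v) for v in fields(16 + 80 + 8 + 8, 8)]
            dig_min = [int(v) for v in fields(16 + 80 + 8 + 16, 8)]
            dig_max = [int(v) for v in fields(16 + 80 + 8 + 24, 8)]
            n_per_rec = [int(v) for v in fields(16 + 80 + 8 + 32 + 80, 8)]
        except ValueError as exc:
            raise FormatError(f"corrupt EDF signal header in {path}: {exc}") from None

        raw: List[List[np.ndarray]] = [[] for _ in range(ns)]
        for _ in range(n_records):
            for i in range(ns):
                buf = _read_exact(fh, 2 * n_per_rec[i], f"samples of {labels[i]!r}")
                raw[i].append(np.frombuffer(buf, dtype="<i2"))

    out: Dict[str, Waveform] = {}
    for i in range(ns):
        dig = np.concatenate(raw[i]).astype(float)
        scale = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        phys = (dig - dig_min[i]) * scale + phys_min[i]
        fs = n_per_rec[i] / rec_duration
        out[labels[i]] = Waveform(labels[i], phys, fs, units=units[i])
    return out
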
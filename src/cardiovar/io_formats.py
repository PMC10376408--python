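"""Readers and writers for every external representation the pipeline touches.

Waveforms travel as CSV (one column per channel, mandatory header row,
comma separator, ``.`` decimal, UTF-8) or as EDF.  Tabular results use a
long-format CSV with the fixed column order
``subject, group, variable, value, units``.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from . import _edf
from .core import FormatError, ParseError, ValidationError, Waveform

#: column order of every results table written by this package
RESULT_COLUMNS = ("subject", "group", "variable", "value", "units")


def read_waveform_csv(
    path: Union[str, os.PathLike],
    column_map: Mapping[str, str],
    sampling_rate: float,
    units: Mapping[str, str] | None = None,
    start_time: float = 0.0,
) -> Union[Waveform, Dict[str, Waveform]]:
    """Read waveform channels from a CSV file.

    Parameters
    ----------
    column_map
        Maps channel name -> CSV column header.
    sampling_rate
        Sampling rate in Hz shared by every channel in the file.
    units
        Optional channel name -> unit string.

    Returns a single ``Waveform`` when ``column_map`` has one entry,
    otherwise a dict keyed by channel name.
    """
    if not sampling_rate > 0:
        raise ValidationError(f"sampling_rate must be > 0, got {sampling_rate}")
    if not column_map:
        raise ValidationError("column_map must name at least one channel")
    if not os.path.exists(path):
        raise FileNotFoundError(path)

    frame = pd.read_csv(path, dtype=str)
    missing = [col for col in column_map.values() if col not in frame.columns]
    if missing:
        raise FormatError(
            f"{path}: missing column(s) {missing}; file has {list(frame.columns)}"
        )

    units = dict(units or {})
    out: Dict[str, Waveform] = {}
    for channel, col in column_map.items():
        raw = frame[col].to_numpy()
        try:
            # numpy's parser is correctly rounded, so CSV round trips are exact
            values = raw.astype(float)
        except (ValueError, TypeError):
            for row, cell in enumerate(raw):
                try:
                    float(cell)
                except (ValueError, TypeError):
                    raise ParseError(
                        f"{path}: column {col!r} has a non-numeric value "
                        f"{cell!r} at data row {row}",
                        row=row,
                    ) from None
            raise  # pragma: no cover - unreachable
        bad = np.flatnonzero(~np.isfinite(values))
        if bad.size:
            row = int(bad[0])
            raise ParseError(
                f"{path}: column {col!r} has a non-finite value "
                f"{raw[row]!r} at data row {row}",
                row=row,
            )
        out[channel] = Waveform(
            channel, values, sampling_rate, start_time=start_time,
            units=units.get(channel, ""),
        ).require_finite()
    if len(out) == 1:
        return next(iter(out.values()))
    return out


def write_waveform_csv(
    waveforms: Union[Waveform, Sequence[Waveform]],
    path: Union[str, os.PathLike],
) -> None:
    """Write one or more equal-rate waveforms as a headed CSV.

    Values are written with ``repr`` precision so that a CSV round trip
    reproduces the float64 samples bit-exactly.
    """
    if isinstance(waveforms, Waveform):
        waveforms = [waveforms]
    if not waveforms:
        raise ValidationError("no waveforms to write")
    n = waveforms[0].n_samples
    fs = waveforms[0].sampling_rate
    for w in waveforms:
        if w.n_samples != n or w.sampling_rate != fs:
            raise ValidationError("all channels in one CSV must share length and rate")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(w.channel_name for w in waveforms) + "\n")
        cols = [w.samples for w in waveforms]
        for i in range(n):
            fh.write(",".join(repr(float(col[i])) for col in cols) + "\n")


def read_waveform_edf(path: Union[str, os.PathLike], channel_name: str) -> Waveform:
    """Read one channel of an EDF file (physical values, header rate)."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    channels = _edf.read_edf(path)
    if channel_name not in channels:
        raise KeyError(
            f"{path}: no channel {channel_name!r}; available: {sorted(channels)}"
        )
    return channels[channel_name].require_finite()


def write_waveform_edf(
    waveforms: Union[Waveform, Sequence[Waveform]],
    path: Union[str, os.PathLike],
) -> None:
    """Write waveforms as an EDF file (16-bit quantized physical values)."""
    if isinstance(waveforms, Waveform):
        waveforms = [waveforms]
    _edf.write_edf(list(waveforms), path)


def _coerce_results(results) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        frame = results.copy()
    else:
        frame = pd.DataFrame(list(results))
    if frame.empty:
        raise ValidationError("refusing to write an empty results table")
    missing = [c for c in RESULT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"results table is missing column(s) {missing}")
    frame = frame.loc[:, list(RESULT_COLUMNS)]
    dup = frame.duplicated(subset=["subject", "variable"])
    if dup.any():
        pair = frame.loc[dup.idxmax(), ["subject", "variable"]].tolist()
        raise ValidationError(f"duplicate (subject, variable) entry {tuple(pair)}")
    return frame


def write_results_table(results, path: Union[str, os.PathLike]) -> None:
    """Write a long-format results table (see ``RESULT_COLUMNS``).

    ``results`` may be a DataFrame or an iterable of row dicts.  Values
    are written with ``repr`` precision so a read-back equals the input.
    """
    frame = _coerce_results(results)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(RESULT_COLUMNS) + "\n")
        for row in frame.itertuples(index=False):
            fh.write(
                f"{row.subject},{row.group},{row.variable},"
                f"{repr(float(row.value))},{row.units}\n"
            )


def read_results_table(path: Union[str, os.PathLike]) -> pd.DataFrame:
    """Read a results table written by :func:`write_results_table`."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in RESULT_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    try:
        frame["value"] = frame["value"].to_numpy().astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric value column: {exc}") from None
    return frame.loc[:, list(RESULT_COLUMNS)]


def autonomic_rows(
    subject: str, group: str, lf_power: float, hf_power: float, lf_hf: float
) -> Iterable[dict]:
    """Expand one window's autonomic indices into three table rows."""
    yield dict(subject=subject, group=group, variable="LF", value=lf_power, units="mmHg^2")
    yield dict(subject=subject, group=group, variable="HF", value=hf_power, units="bpm^2")
    yield dict(subject=subject, group=group, variable="LF/HF", value=lf_hf, units="")
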
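"""Readers and writers for the external file formats.

Canonical on-disk formats (all plain text):

* IBI CSV — header ``timestamp_ms,ibi_ms``; one row per interval, the
  timestamp marking the beat that closes the interval.
* HRV Logger dialect — header ``timestamp,rr``; the logger's beat-stamped
  RR export, mapped onto the canonical columns on read.
* Criterion text export — whitespace/tab separated ``timestamp ibi`` lines,
  ``#`` comment lines skipped.
* Peaks CSV — header ``peak_time_ms``.
* Accelerometer CSV — header ``time_ms,x,y,z`` (ADC counts; calibration
  ranges come from configuration, not the file).
* Condition table — CSV ``participant_id,condition,start_ms,end_ms``.
"""

from __future__ import annotations

import io
import warnings
from pathlib import Path
from typing import Dict, List, Union

import numpy as np
import pandas as pd

from .errors import IngestError
from .model import AccelRaw, ConditionWindow, IbiSeries, PeakTrain

__all__ = [
    "read_ibi_csv",
    "write_ibi_csv",
    "peaks_to_ibis",
    "read_peaks_csv",
    "write_peaks_csv",
    "normalize_timestamps",
    "read_accel_csv",
    "read_conditions_csv",
]

_DIALECTS = {
    # dialect -> (timestamp column, ibi column, separator, comment char)
    "generic": ("timestamp_ms", "ibi_ms", ",", None),
    "hrv_logger": ("timestamp", "rr", ",", None),
    "criterion_txt": ("timestamp", "ibi", r"\s+", "#"),
}


def _numeric_or_raise(raw: pd.Series, col: str, path) -> np.ndarray:
    vals = pd.to_numeric(raw, errors="coerce")
    bad = vals.isna() & raw.notna()
    if bad.any():
        # +2: one for the header, one for 0- vs 1-based line numbering
        line = int(bad.idxmax()) + 2
        raise IngestError(
            f"{path}: unparseable {col} value {raw[bad.idxmax()]!r} at line {line}"
        )
    if vals.isna().any():
        line = int(vals.isna().idxmax()) + 2
        raise IngestError(f"{path}: missing {col} value at line {line}")
    return vals.to_numpy()


def read_ibi_csv(
    path: Union[str, Path],
    dialect: str = "generic",
    device_id: str = "",
    participant_id: str = "",
) -> IbiSeries:
    """Read a timestamped IBI export into an :class:`IbiSeries`.

    Rows are sorted by timestamp; duplicate timestamps collapse to the first
    occurrence with a warning. An empty file yields an empty series.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(_DIALECTS)}")
    t_col, ibi_col, sep, comment = _DIALECTS[dialect]
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep, comment=comment, engine="python", dtype=str)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=[t_col, ibi_col])
    if df.empty:
        return IbiSeries(device_id, participant_id, [], [])
    df.columns = [c.strip().lower() for c in df.columns]
    for col in (t_col, ibi_col):
        if col not in df.columns:
            raise IngestError(f"{path}: missing required column {col!r} for dialect {dialect!r}")
    t = _numeric_or_raise(df[t_col], t_col, path)
    ibi = _numeric_or_raise(df[ibi_col], ibi_col, path)
    order = np.argsort(t, kind="stable")
    t, ibi = t[order], ibi[order]
    t_int = np.round(t).astype(np.int64)
    keep = np.ones(len(t_int), dtype=bool)
    keep[1:] = np.diff(t_int) > 0
    if not keep.all():
        warnings.warn(
            f"{path}: {int((~keep).sum())} duplicate timestamp(s) dropped (kept first)",
            stacklevel=2,
        )
    return IbiSeries(device_id, participant_id, t_int[keep], ibi[keep])


def write_ibi_csv(series: IbiSeries, path: Union[str, Path]) -> None:
    """Write an IbiSeries in the canonical ``timestamp_ms,ibi_ms`` dialect."""
    df = pd.DataFrame({"timestamp_ms": series.onsets, "ibi_ms": series.ibis})
    df.to_csv(path, index=False)


def peaks_to_ibis(
    peaks: PeakTrain, participant_id: str = ""
) -> IbiSeries:
    """Convert systolic-peak timestamps to interbeat intervals.

    ``ibis[i] = peak_times[i+1] - peak_times[i]``; each interval is anchored
    at the beat that closes it, so ``onsets = peak_times[1:]``. Fewer than
    two peaks yield an empty series.
    """
    t = peaks.peak_times
    if len(t) < 2:
        return IbiSeries(peaks.device_id, participant_id, [], [])
    return IbiSeries(
        peaks.device_id,
        participant_id,
        t[1:],
        np.diff(t).astype(np.float64),
    )


def read_peaks_csv(path: Union[str, Path], device_id: str = "") -> PeakTrain:
    """Read a one-column ``peak_time_ms`` CSV into a :class:`PeakTrain`."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        return PeakTrain(device_id, [])
    if df.empty:
        return PeakTrain(device_id, [])
    df.columns = [c.strip().lower() for c in df.columns]
    if "peak_time_ms" not in df.columns:
        raise IngestError(f"{path}: missing required column 'peak_time_ms'")
    t = _numeric_or_raise(df["peak_time_ms"], "peak_time_ms", path)
    t = np.unique(np.round(t).astype(np.int64))  # sorted, de-duplicated
    return PeakTrain(device_id, t)


def write_peaks_csv(peaks: PeakTrain, path: Union[str, Path]) -> None:
    pd.DataFrame({"peak_time_ms": peaks.peak_times}).to_csv(path, index=False)


def normalize_timestamps(series: IbiSeries, clock_offset_ms: int) -> IbiSeries:
    """Shift every onset by ``clock_offset_ms``; IBI values are untouched."""
    return series.shifted(int(clock_offset_ms))


def read_accel_csv(
    path: Union[str, Path], digital_range: float, physical_range: float
) -> AccelRaw:
    """Read a ``time_ms,x,y,z`` counts CSV; calibration comes from config."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("time_ms", "x", "y", "z"):
        if col not in df.columns:
            raise IngestError(f"{path}: missing required column {col!r}")
    t = np.round(_numeric_or_raise(df["time_ms"], "time_ms", path)).astype(np.int64)
    cols = [_numeric_or_raise(df[c], c, path) for c in ("x", "y", "z")]
    return AccelRaw(t, *cols, digital_range=digital_range, physical_range=physical_range)


def read_conditions_csv(path: Union[str, Path]) -> Dict[str, List[ConditionWindow]]:
    """Read a condition table; returns windows grouped by participant."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("participant_id", "condition", "start_ms", "end_ms"):
        if col not in df.columns:
            raise IngestError(f"{path}: missing required column {col!r}")
    out: Dict[str, List[ConditionWindow]] = {}
    start = _numeric_or_raise(df["start_ms"], "start_ms", path)
    end = _numeric_or_raise(df["end_ms"], "end_ms", path)
    for i, row in df.iterrows():
        win = ConditionWindow(str(row["condition"]), int(start[i]), int(end[i]))
        pid = str(row["participant_id"])
        names = {w.name for w in out.get(pid, [])}
        if win.name in names:
            raise IngestError(
                f"{path}: duplicate condition {win.name!r} for participant {pid!r}"
            )
        out.setdefault(pid, []).append(win)
    return out
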
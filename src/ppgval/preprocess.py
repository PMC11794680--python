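"""Artifact detection and correction for interbeat-interval segments.

Two rules define an artifact:

1. a fixed physiological range — intervals shorter than 300 ms or longer
   than 2000 ms are implausible and removed;
2. the Karlsson neighbour-mean rule — an interior interval whose deviation
   from the mean of its two neighbours exceeds a fractional threshold ``c``
   is an outlier (the first and last intervals are never flagged).

Flagged values are replaced in place by linear interpolation between the
nearest unflagged neighbours over beat *index* (runs of consecutive flags
interpolate across the run; flagged extremes take the nearest unflagged
value). The Karlsson threshold starts at 0.25 and, per participant, is
escalated in 0.05 steps until the criterion (ECG) segments — already
visually scored and clean — show no outliers; that personalised threshold
is then shared across all of the participant's devices and conditions,
which avoids over-correcting individuals with naturally high variability.
"""

from __future__ import annotations

import numpy as np

from .errors import PreprocessError
from .model import CleanResult, IbiSeries, SegmentedRecord

__all__ = [
    "range_filter_flags",
    "karlsson_flags",
    "correct",
    "clean_segment",
    "tune_threshold",
]

RANGE_LOW_MS = 300.0
RANGE_HIGH_MS = 2000.0
KARLSSON_START = 0.25
KARLSSON_STEP = 0.05
KARLSSON_CAP = 1.0


def range_filter_flags(
    ibis: np.ndarray, low: float = RANGE_LOW_MS, high: float = RANGE_HIGH_MS
) -> np.ndarray:
    """Flag intervals strictly outside [low, high] ms; boundary values are kept."""
    ibis = np.asarray(ibis, dtype=float)
    return (ibis < low) | (ibis > high)


def karlsson_flags(ibis: np.ndarray, c: float) -> np.ndarray:
    """Flag interior intervals deviating from their neighbour mean by more than ``c``.

    For interval ``i`` with neighbour mean ``m = (ibi[i-1] + ibi[i+1]) / 2``
    the flag is ``|ibi[i] - m| > c * m``. Neighbour means use the original
    values; all flags are decided simultaneously (no sequential
    re-evaluation). Series shorter than 3 yield all-false flags.
    """
    if c <= 0:
        raise ValueError("threshold coefficient must be positive")
    ibis = np.asarray(ibis, dtype=float)
    flags = np.zeros(len(ibis), dtype=bool)
    if len(ibis) < 3:
        return flags
    m = (ibis[:-2] + ibis[2:]) / 2.0
    flags[1:-1] = np.abs(ibis[1:-1] - m) > c * m
    return flags


def correct(series: IbiSeries, flags: np.ndarray) -> CleanResult:
    """Replace flagged intervals by linear interpolation over beat index.

    Onsets are untouched; the interpolated mask records replacements (on top
    of any already present). Raises :class:`PreprocessError` when every
    interval is flagged, since interpolation then has nothing to anchor to.
    """
    flags = np.asarray(flags, dtype=bool)
    if len(flags) != len(series):
        raise ValueError("flags must match the series length")
    if len(series) == 0 or not flags.any():
        return CleanResult(series.replace(), 0, np.nan)
    good = ~flags
    if not good.any():
        raise PreprocessError(
            f"{series.participant_id}/{series.device_id}: every interval flagged; "
            "nothing to anchor interpolation"
        )
    idx = np.arange(len(series), dtype=float)
    new_ibis = series.ibis.copy()
    # np.interp constant-extends beyond the outermost anchors, which is
    # exactly the required edge rule
    new_ibis[flags] = np.interp(idx[flags], idx[good], series.ibis[good])
    mask = series.interpolated_mask | flags
    out = series.replace(ibis=new_ibis, interpolated_mask=mask)
    return CleanResult(out, int(flags.sum()), np.nan)


def clean_segment(
    series: IbiSeries,
    threshold: float,
    low: float = RANGE_LOW_MS,
    high: float = RANGE_HIGH_MS,
) -> CleanResult:
    """Full cleaning of one segment: range rule first, then one Karlsson pass.

    Both kinds of flagged-and-replaced intervals count as artifacts;
    ``n_artifacts`` is the union of the two rules' flags (equivalently the
    number of true entries in the final mask for a freshly ingested input).
    """
    if len(series) == 0:
        return CleanResult(series.replace(), 0, threshold)
    f_range = range_filter_flags(series.ibis, low, high)
    step1 = correct(series, f_range)
    f_karl = karlsson_flags(step1.series.ibis, threshold)
    step2 = correct(step1.series, f_karl)
    n = int((f_range | f_karl).sum())
    return CleanResult(step2.series, n, threshold)


def tune_threshold(
    criterion_segments: SegmentedRecord,
    start: float = KARLSSON_START,
    step: float = KARLSSON_STEP,
    cap: float = KARLSSON_CAP,
    low: float = RANGE_LOW_MS,
    high: float = RANGE_HIGH_MS,
) -> float:
    """Find the per-participant Karlsson threshold on criterion data.

    Returns the smallest coefficient in {start, start+step, ...} <= cap for
    which the Karlsson rule flags nothing on any criterion segment (after
    range filtering). Raises :class:`PreprocessError` when the cap is
    reached with flags remaining — the criterion recording then needs
    manual review.
    """
    non_empty = [s for s in criterion_segments.segments.values() if len(s)]
    if not non_empty:
        raise PreprocessError(
            f"{criterion_segments.participant_id}: criterion record has no "
            "non-empty segments to tune on"
        )
    filtered = []
    for seg in non_empty:
        flags = range_filter_flags(seg.ibis, low, high)
        filtered.append(correct(seg, flags).series.ibis)
    n_steps = int(np.floor((cap - start) / step + 1e-9)) + 1
    for i in range(n_steps):
        c = round(start + i * step, 10)
        if all(not karlsson_flags(ibis, c).any() for ibis in filtered):
            return c
    raise PreprocessError(
        f"{criterion_segments.participant_id}: Karlsson threshold cap {cap} "
        "reached with outliers remaining on the criterion; manual review advised"
    )
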
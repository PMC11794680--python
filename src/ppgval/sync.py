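"""Device-to-criterion time alignment and condition segmentation.

The original study aligned streams by maximising cross-correlation under
visual inspection; here that step is automated. Both beat series are turned
into instantaneous-heart-rate step functions sampled on a uniform grid
(default 4 Hz, mirroring the spectral resampling rate) and the integer-grid
lag maximising the Pearson correlation of the overlapping samples is
returned. A ``lag_override`` escape hatch in the pipeline config covers
recordings where the automatic estimate needs manual review.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np

from .errors import ConfigError, SyncError
from .io_ingest import normalize_timestamps
from .model import ConditionWindow, IbiSeries, SegmentedRecord

__all__ = ["LagEstimate", "estimate_lag", "apply_lag", "segment"]

#: below this peak correlation the estimate is flagged for manual review
LOW_CORRELATION = 0.3
#: minimum overlap required between the two streams, seconds
MIN_OVERLAP_S = 60.0
#: intervals outside the physiological range (same bounds as the artifact
#: range rule) are gaps or merged/split beats; their span carries no usable
#: rate information for the correlation search
MIN_INTERVAL_MS = 300.0
MAX_INTERVAL_MS = 2000.0


@dataclass(frozen=True)
class LagEstimate:
    """Result of cross-correlation lag search.

    ``lag_ms`` is how far the device clock runs *ahead* of the criterion
    clock: subtracting it from the device onsets aligns the streams.
    """

    lag_ms: int
    correlation: float
    low_confidence: bool


def _rate_step(series: IbiSeries, t: np.ndarray) -> np.ndarray:
    """Instantaneous HR (bpm) held piecewise-constant between beats.

    For grid time ``t`` inside the series span the value is 60000/ibi of the
    interval containing ``t``; outside the span, and across intervals
    outside the physiological range (gaps, merged or split beats), it is NaN.
    """
    out = np.full(len(t), np.nan)
    if len(series) == 0:
        return out
    onsets = series.onsets.astype(np.float64)
    start = onsets[0] - series.ibis[0]
    # interval i covers (onsets[i] - ibis[i], onsets[i]]
    idx = np.searchsorted(onsets, t, side="left")
    inside = (t >= start) & (t <= onsets[-1]) & (idx < len(onsets))
    vals = series.ibis[idx[inside]]
    ok = (vals >= MIN_INTERVAL_MS) & (vals <= MAX_INTERVAL_MS)
    # merged beats (~2x the heart period) and split beats (fractions of it)
    # survive the absolute bounds at slow heart rates; a relative bound
    # against the series median screens them too
    med = float(np.median(series.ibis))
    ok &= (vals >= 0.65 * med) & (vals <= 1.5 * med)
    out[inside] = np.where(ok, 60000.0 / vals, np.nan)
    return out


def estimate_lag(
    device: IbiSeries,
    criterion: IbiSeries,
    max_lag_s: float = 60.0,
    grid_hz: float = 4.0,
) -> LagEstimate:
    """Estimate the constant clock offset of ``device`` relative to ``criterion``.

    Scans integer-grid lags in ``[-max_lag_s, +max_lag_s]``, picking the one
    maximising the Pearson correlation of the overlapping grid samples; ties
    break toward the smallest ``|lag|``. Raises :class:`SyncError` when the
    streams overlap by less than 60 s at every candidate lag; flags the
    result ``low_confidence`` when the best correlation is below 0.3.
    """
    if len(device) == 0 or len(criterion) == 0:
        raise SyncError("cannot synchronize an empty series")
    step_ms = 1000.0 / grid_hz
    max_k = int(round(max_lag_s * grid_hz))
    t0 = criterion.onsets[0] - criterion.ibis[0]
    t1 = float(criterion.onsets[-1])
    grid = np.arange(t0, t1 + step_ms / 2, step_ms)
    ref = _rate_step(criterion, grid)
    min_samples = int(np.ceil(MIN_OVERLAP_S * grid_hz))

    best_k = None
    best_r = -np.inf
    any_overlap = False
    # ordered by |k| so strict improvement keeps the smallest-|lag| winner
    for k in sorted(range(-max_k, max_k + 1), key=abs):
        dev = _rate_step(device, grid + k * step_ms)
        ok = np.isfinite(ref) & np.isfinite(dev)
        if ok.sum() < min_samples:
            continue
        any_overlap = True
        a, b = ref[ok], dev[ok]
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            # flat overlap carries no alignment information
            r = 0.0
        else:
            r = float(np.corrcoef(a, b)[0, 1])
        if r > best_r:
            best_r, best_k = r, k
    if not any_overlap or best_k is None:
        raise SyncError(
            f"streams overlap by less than {MIN_OVERLAP_S:.0f} s within "
            f"+/-{max_lag_s:.0f} s; cannot synchronize"
        )
    low = best_r < LOW_CORRELATION
    if low:
        warnings.warn(
            f"lag estimate has low correlation ({best_r:.2f} < {LOW_CORRELATION}); "
            "manual review advised",
            stacklevel=2,
        )
    return LagEstimate(int(round(best_k * step_ms)), best_r, low)


def apply_lag(device: IbiSeries, lag_ms: int) -> IbiSeries:
    """Shift the device onto the criterion clock by subtracting ``lag_ms``."""
    return normalize_timestamps(device, -int(lag_ms))


def segment(series: IbiSeries, windows: Sequence[ConditionWindow]) -> SegmentedRecord:
    """Slice a series into condition windows.

    Membership is by interval onset in the half-open window ``[start, end)``;
    empty segments are retained (needed for "missing" classification
    downstream). Overlapping windows are a configuration error.
    """
    ordered = sorted(windows, key=lambda w: w.start_ms)
    for a, b in zip(ordered, ordered[1:]):
        if b.start_ms < a.end_ms:
            raise ConfigError(f"condition windows {a.name!r} and {b.name!r} overlap")
    names = [w.name for w in windows]
    if len(set(names)) != len(names):
        raise ConfigError("condition names must be unique")
    segments: Dict[str, IbiSeries] = {}
    for w in windows:
        sel = (series.onsets >= w.start_ms) & (series.onsets < w.end_ms)
        segments[w.name] = IbiSeries(
            series.device_id,
            series.participant_id,
            series.onsets[sel],
            series.ibis[sel],
            series.interpolated_mask[sel],
        )
    return SegmentedRecord(series.participant_id, series.device_id, segments)
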
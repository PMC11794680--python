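"""Core data model: timestamped interbeat-interval series and friends.

All times are integer milliseconds since the Unix epoch (UTC). An interbeat
interval (IBI) is anchored at the time of the beat that *closes* it: the
onset stored for interval ``i`` is the timestamp of the second of the two
beats whose spacing the interval measures. This convention is applied
consistently everywhere, including condition segmentation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigError

__all__ = [
    "IbiSeries",
    "PeakTrain",
    "ConditionWindow",
    "AccelRaw",
    "AccelSeries",
    "SegmentedRecord",
    "CleanResult",
    "FeatureRow",
    "QualityLabel",
    "AgreementStats",
]


def _as_1d(x, dtype) -> np.ndarray:
    arr = np.asarray(x, dtype=dtype)
    if arr.ndim != 1:
        raise ValueError(f"expected a 1-D array, got shape {arr.shape}")
    return arr


@dataclass
class IbiSeries:
    """A timestamped sequence of interbeat intervals for one participant/device.

    Parameters
    ----------
    device_id, participant_id : str
        Free-text labels.
    onsets : array of int64
        Milliseconds since the Unix epoch; one per interval, the time of the
        beat closing that interval. Strictly increasing.
    ibis : array of float64
        Interval durations in milliseconds, all positive.
    interpolated_mask : array of bool, optional
        Per-interval flag marking values replaced during artifact correction.
        All-false on freshly ingested data.
    """

    device_id: str
    participant_id: str
    onsets: np.ndarray
    ibis: np.ndarray
    interpolated_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.onsets = _as_1d(self.onsets, np.int64)
        self.ibis = _as_1d(self.ibis, np.float64)
        if self.interpolated_mask is None:
            self.interpolated_mask = np.zeros(len(self.onsets), dtype=bool)
        else:
            self.interpolated_mask = _as_1d(self.interpolated_mask, bool)
        n = len(self.onsets)
        if len(self.ibis) != n or len(self.interpolated_mask) != n:
            raise ValueError("onsets, ibis and interpolated_mask must have equal length")
        if n and np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if n and np.any(self.ibis <= 0):
            raise ValueError("all IBIs must be positive")

    def __len__(self) -> int:
        return len(self.onsets)

    @property
    def start_ms(self) -> int:
        """Time of the beat opening the first interval."""
        if not len(self):
            raise ValueError("empty series has no start")
        return int(self.onsets[0] - round(self.ibis[0]))

    @property
    def end_ms(self) -> int:
        if not len(self):
            raise ValueError("empty series has no end")
        return int(self.onsets[-1])

    def shifted(self, offset_ms: int) -> "IbiSeries":
        """Return a copy with every onset shifted by ``offset_ms``."""
        return dataclasses.replace(self, onsets=self.onsets + np.int64(offset_ms))

    def replace(self, **kwargs) -> "IbiSeries":
        return dataclasses.replace(self, **kwargs)


@dataclass
class PeakTrain:
    """Timestamps of detected systolic peaks (or ECG R-peaks) for one device."""

    device_id: str
    peak_times: np.ndarray  # ms since epoch, strictly increasing

    def __post_init__(self) -> None:
        self.peak_times = _as_1d(self.peak_times, np.int64)
        if len(self.peak_times) and np.any(np.diff(self.peak_times) <= 0):
            raise ValueError("peak times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.peak_times)


@dataclass(frozen=True)
class ConditionWindow:
    """A named experimental-condition time window, half-open [start, end)."""

    name: str
    start_ms: int
    end_ms: int

    def __post_init__(self) -> None:
        if not self.start_ms < self.end_ms:
            raise ConfigError(
                f"condition {self.name!r}: start ({self.start_ms}) must precede "
                f"end ({self.end_ms})"
            )

    @property
    def duration_ms(self) -> int:
        return self.end_ms - self.start_ms


@dataclass
class AccelRaw:
    """Raw tri-axial accelerometer samples in ADC counts, plus calibration."""

    times: np.ndarray  # ms since epoch
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    digital_range: float  # counts spanning the full scale
    physical_range: float  # g units spanning the full scale

    def __post_init__(self) -> None:
        self.times = _as_1d(self.times, np.int64)
        self.x = _as_1d(self.x, np.float64)
        self.y = _as_1d(self.y, np.float64)
        self.z = _as_1d(self.z, np.float64)
        n = len(self.times)
        if not (len(self.x) == len(self.y) == len(self.z) == n):
            raise ValueError("accelerometer channels must have equal length")
        if self.digital_range <= 0 or self.physical_range <= 0:
            raise ConfigError("calibration ranges must be positive")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class AccelSeries:
    """Calibrated acceleration in g units with per-sample Euclidean magnitude."""

    times: np.ndarray
    gx: np.ndarray
    gy: np.ndarray
    gz: np.ndarray
    magnitude: np.ndarray

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class SegmentedRecord:
    """Per-condition slices of one participant/device IbiSeries."""

    participant_id: str
    device_id: str
    segments: Dict[str, IbiSeries]

    def __iter__(self):
        return iter(self.segments.items())


@dataclass
class CleanResult:
    """Outcome of artifact correction on one segment.

    ``n_artifacts`` equals the number of true entries in the corrected
    series' ``interpolated_mask``; correction replaces values in place, so
    the series keeps its original length.
    """

    series: IbiSeries
    n_artifacts: int
    threshold_used: float


@dataclass
class FeatureRow:
    """The three outcome features for one participant x device x condition.

    Absent features (empty or too-short segments) are ``nan``.
    """

    participant_id: str
    device_id: str
    condition: str
    hr: float  # beats per minute
    rmssd: float  # ms
    hf: float  # ms^2
    n_ibis: int
    quality: str = "acceptable"


@dataclass
class QualityLabel:
    """Signal-quality classification of one segment."""

    label: str  # acceptable | poor | missing
    detection_rate: float  # percent; nan when missing
    artifact_fraction: float  # percent of detected IBIs; nan when missing
    reason: str = ""


@dataclass
class AgreementStats:
    """Device-vs-criterion agreement for one feature in one condition."""

    maape: float  # percent, in [0, 100*pi/2]
    maape_ci: Tuple[float, float]
    slope: float
    intercept: float
    r: float
    p_raw: float
    p_adjusted: float
    stderr: float
    r_band: str
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    ci_bias: Tuple[float, float]
    ci_loa_low: Tuple[float, float]
    ci_loa_high: Tuple[float, float]
    n: int
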
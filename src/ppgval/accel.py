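"""Accelerometer processing: counts to g, gravity removal, movement summary.

Raw tri-axial counts are scaled by the sensitivity (physical range over
digital range), high-pass filtered per axis (first-order Butterworth,
0.1 Hz cutoff, applied forward-backward for zero phase — filtering lag
would smear condition boundaries), combined into the per-sample Euclidean
magnitude, and averaged within each condition window.
"""

from __future__ import annotations

from typing import Dict, Sequence, Tuple

import numpy as np
from scipy import signal

from .errors import ConfigError, PpgvalError
from .model import AccelRaw, AccelSeries, ConditionWindow

__all__ = ["adc_to_g", "highpass", "magnitude_and_mean", "movement_summary"]

CUTOFF_HZ = 0.1
FILTER_ORDER = 1


def adc_to_g(raw: AccelRaw) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convert ADC counts to g per axis: count x (physical_range / digital_range)."""
    if raw.digital_range <= 0 or raw.physical_range <= 0:
        raise ConfigError("accelerometer calibration ranges must be positive")
    s = raw.physical_range / raw.digital_range
    return raw.x * s, raw.y * s, raw.z * s


def highpass(
    x: np.ndarray,
    sample_rate_hz: float,
    cutoff_hz: float = CUTOFF_HZ,
    order: int = FILTER_ORDER,
) -> np.ndarray:
    """Zero-phase Butterworth high-pass; removes the static gravity component."""
    if sample_rate_hz <= 2 * cutoff_hz:
        raise ConfigError(
            f"sample rate {sample_rate_hz} Hz too low for a {cutoff_hz} Hz cutoff"
        )
    sos = signal.butter(order, cutoff_hz, btype="highpass", fs=sample_rate_hz, output="sos")
    padlen = 3 * (2 * order + 1)
    if len(x) <= padlen:
        raise PpgvalError(
            f"signal of {len(x)} samples too short for a stable zero-phase filter"
        )
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float))


def magnitude_and_mean(
    times: np.ndarray,
    gx: np.ndarray,
    gy: np.ndarray,
    gz: np.ndarray,
    windows: Sequence[ConditionWindow],
) -> Dict[str, float]:
    """Per-sample Euclidean magnitude, averaged within each window.

    Windows holding no samples map to NaN.
    """
    mag = np.sqrt(np.asarray(gx) ** 2 + np.asarray(gy) ** 2 + np.asarray(gz) ** 2)
    times = np.asarray(times)
    out: Dict[str, float] = {}
    for w in windows:
        sel = (times >= w.start_ms) & (times < w.end_ms)
        out[w.name] = float(mag[sel].mean()) if sel.any() else float("nan")
    return out


def movement_summary(
    raw: AccelRaw,
    sample_rate_hz: float,
    windows: Sequence[ConditionWindow],
    cutoff_hz: float = CUTOFF_HZ,
    order: int = FILTER_ORDER,
) -> Dict[str, float]:
    """Full chain: calibrate, high-pass each axis, magnitude, condition means."""
    gx, gy, gz = adc_to_g(raw)
    fx = highpass(gx, sample_rate_hz, cutoff_hz, order)
    fy = highpass(gy, sample_rate_hz, cutoff_hz, order)
    fz = highpass(gz, sample_rate_hz, cutoff_hz, order)
    return magnitude_and_mean(raw.times, fx, fy, fz, windows)
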
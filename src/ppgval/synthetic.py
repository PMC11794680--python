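"""Synthetic paired criterion/device streams with known ground truth.

The generator emulates the measurement situation the pipeline is built
for: a clean beat-to-beat (criterion ECG) series whose heart period
carries a respiratory-band sinusoidal modulation (respiratory sinus
arrhythmia) plus beat-to-beat noise, and wearable streams derived from it
by the failure modes PPG devices actually exhibit — missed beats (adjacent
intervals merge), spurious beats (an interval splits), timing jitter,
contiguous dropouts, and a constant clock offset. Corruption operates on
reconstructed beat times, so merge/split semantics are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as _signal

from .errors import ConfigError
from .model import AccelRaw, ConditionWindow, IbiSeries

__all__ = ["SynthConfig", "simulate_criterion", "corrupt", "simulate_accel"]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one simulated recording.

    Defaults model a resting adult: mean heart period 900 ms (~67 bpm),
    respiratory modulation of 50 ms amplitude at 0.25 Hz (15 breaths/min,
    inside the 0.12-0.40 Hz band), 10 ms beat-to-beat noise, five-minute
    duration, and no corruption.
    """

    seed: int = 0
    duration_s: float = 300.0
    mean_ibi_ms: float = 900.0
    rsa_amp_ms: float = 50.0
    rsa_freq_hz: float = 0.25
    noise_sd_ms: float = 10.0
    miss_rate: float = 0.0
    extra_rate: float = 0.0
    jitter_sd_ms: float = 0.0
    dropout_windows: Tuple[Tuple[float, float], ...] = ()
    clock_offset_ms: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.miss_rate <= 1.0 and 0.0 <= self.extra_rate <= 1.0):
            raise ConfigError("miss_rate and extra_rate must lie in [0, 1]")
        if self.rsa_amp_ms < 0 or self.noise_sd_ms < 0 or self.jitter_sd_ms < 0:
            raise ConfigError("amplitudes and noise SDs must be non-negative")
        if self.mean_ibi_ms - self.rsa_amp_ms - 4 * self.noise_sd_ms <= 300.0:
            raise ConfigError(
                "mean_ibi_ms - rsa_amp_ms - 4*noise_sd_ms must exceed 300 ms "
                "so that the truth stays inside the physiological range"
            )
        if self.duration_s <= 0:
            raise ConfigError("duration_s must be positive")


def _truth_rmssd(ibis: np.ndarray) -> float:
    # deliberately spelled out rather than calling features.rmssd: the
    # ground truth must come from an independent code path
    total = 0.0
    for i in range(1, len(ibis)):
        total += (float(ibis[i]) - float(ibis[i - 1])) ** 2
    return float(np.sqrt(total / (len(ibis) - 1))) if len(ibis) > 1 else float("nan")


def simulate_criterion(
    cfg: SynthConfig,
    participant_id: str = "sim",
    device_id: str = "criterion",
    t0_ms: int = 0,
) -> Tuple[IbiSeries, Dict[str, float]]:
    """Generate a clean criterion series and its ground-truth features.

    Beat times accrue iteratively: the next interval is
    ``mean_ibi_ms + rsa_amp_ms * sin(2 pi f t) + Normal(0, noise_sd_ms)``
    with ``t`` the elapsed time in seconds. Returns the realized series and
    a truth dict with ``hr`` and ``rmssd`` computed from the realized
    values (by an independent route) plus ``hf_tone`` — the analytic
    in-band power ``rsa_amp_ms^2 / 2`` of the modulation.
    """
    rng = np.random.default_rng(cfg.seed)
    t = 0.0  # seconds since start
    ibis: List[float] = []
    while t < cfg.duration_s:
        ibi = (
            cfg.mean_ibi_ms
            + cfg.rsa_amp_ms * np.sin(2 * np.pi * cfg.rsa_freq_hz * t)
            + (rng.normal(0.0, cfg.noise_sd_ms) if cfg.noise_sd_ms > 0 else 0.0)
        )
        ibi = max(ibi, 1.0)
        ibis.append(ibi)
        t += ibi / 1000.0
    arr = np.asarray(ibis)
    peaks = t0_ms + np.round(np.concatenate([[0.0], np.cumsum(arr)])).astype(np.int64)
    real_ibis = np.diff(peaks).astype(float)  # after ms rounding
    series = IbiSeries(device_id, participant_id, peaks[1:], real_ibis)
    truth = {
        "hr": 60000.0 * len(real_ibis) / float(np.sum(real_ibis)),
        "rmssd": _truth_rmssd(real_ibis),
        "hf_tone": cfg.rsa_amp_ms**2 / 2.0,
    }
    return series, truth


def corrupt(
    criterion: IbiSeries, cfg: SynthConfig, device_id: str = "device"
) -> IbiSeries:
    """Derive a wearable-like stream from the criterion.

    Applied in order to the reconstructed beat times: constant clock
    offset; per-beat deletion with probability ``miss_rate``; per-interval
    insertion with probability ``extra_rate`` at a uniform split point;
    Gaussian timing jitter; removal of all beats inside
    ``dropout_windows`` (ms since epoch). Deterministic under the config
    seed (a stream decoupled from the criterion's own draws).
    """
    if len(criterion) == 0:
        raise ConfigError("cannot corrupt an empty criterion series")
    rng = np.random.default_rng(cfg.seed + 1)
    first = criterion.onsets[0] - criterion.ibis[0]
    peaks = np.concatenate([[first], criterion.onsets]).astype(float)
    peaks = peaks + cfg.clock_offset_ms
    if cfg.miss_rate > 0:
        peaks = peaks[rng.random(len(peaks)) >= cfg.miss_rate]
    if cfg.extra_rate > 0 and len(peaks) >= 2:
        inserted = []
        gaps = np.diff(peaks)
        split = rng.random(len(gaps)) < cfg.extra_rate
        frac = rng.uniform(0.2, 0.8, len(gaps))  # keep both halves non-trivial
        for i in np.nonzero(split)[0]:
            inserted.append(peaks[i] + frac[i] * gaps[i])
        if inserted:
            peaks = np.sort(np.concatenate([peaks, inserted]))
    if cfg.jitter_sd_ms > 0:
        peaks = np.sort(peaks + rng.normal(0.0, cfg.jitter_sd_ms, len(peaks)))
    for start, end in cfg.dropout_windows:
        peaks = peaks[(peaks < start) | (peaks >= end)]
    peaks = np.round(peaks).astype(np.int64)
    # rounding/jitter can collide adjacent beats; keep strictly increasing
    if len(peaks):
        keep = np.ones(len(peaks), dtype=bool)
        keep[1:] = np.diff(peaks) > 0
        peaks = peaks[keep]
    if len(peaks) < 2:
        return IbiSeries(device_id, criterion.participant_id, [], [])
    return IbiSeries(
        device_id,
        criterion.participant_id,
        peaks[1:],
        np.diff(peaks).astype(float),
    )


def simulate_accel(
    windows: Sequence[ConditionWindow],
    movement_levels: Dict[str, float],
    sample_rate_hz: float,
    cfg: SynthConfig,
    digital_range: float = 65536.0,
    physical_range: float = 4.0,
) -> AccelRaw:
    """Tri-axial counts: band-limited noise over a constant 1 g gravity vector.

    Per window, zero-mean Gaussian noise on each axis is band-limited to
    0.3 Hz - min(8, 0.45*fs) Hz and scaled so that the *mean magnitude* of
    the noise vector equals the requested movement level in g (the quantity
    the per-condition movement summary reports). Gravity sits on the z
    axis; emitted as ADC counts under the given calibration.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    t0 = min(w.start_ms for w in windows)
    t1 = max(w.end_ms for w in windows)
    step = 1000.0 / sample_rate_hz
    times = np.arange(t0, t1, step)
    n = len(times)
    axes = np.zeros((3, n))
    low, high = 0.3, min(8.0, 0.45 * sample_rate_hz)
    sos = _signal.butter(2, [low, high], btype="bandpass", fs=sample_rate_hz, output="sos")
    # E|v| for an isotropic Gaussian vector with per-axis sd s is s*2*sqrt(2/pi)
    mean_mag_per_sd = 2.0 * np.sqrt(2.0 / np.pi)
    for w in windows:
        level = movement_levels.get(w.name, 0.0)
        sel = (times >= w.start_ms) & (times < w.end_ms)
        if level <= 0 or sel.sum() < 30:
            continue
        target_sd = level / mean_mag_per_sd
        for ax in range(3):
            raw = rng.normal(0.0, 1.0, int(sel.sum()))
            filt = _signal.sosfiltfilt(sos, raw)
            sd = filt.std()
            if sd > 0:
                axes[ax, sel] = filt * (target_sd / sd)
    axes[2] += 1.0  # gravity
    scale = digital_range / physical_range
    counts = np.round(axes * scale)
    return AccelRaw(
        np.round(times).astype(np.int64),
        counts[0],
        counts[1],
        counts[2],
        digital_range=digital_range,
        physical_range=physical_range,
    )
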
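"""End-to-end orchestration: ingest -> sync -> segment -> clean -> features
-> quality -> accel -> agreement, plus synthetic study generation.

Two entry points:

* :func:`analyze_cohort` — pure in-memory analysis of already-ingested
  streams; everything downstream of file I/O, fully deterministic.
* :func:`run_pipeline` — reads a :class:`StudyConfig` (typically from
  YAML), resolves input files, runs the cohort analysis and writes the
  report bundle (CSV/Markdown tables, a machine-readable JSON of all
  statistics, optional plots, and a run log of every parameter used).

Per-participant failures are logged and skipped rather than fatal: device
counts per cell vary in real validation studies, and the tables report n
per cell.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import accel as accel_mod
from . import agreement as agreement_mod
from . import features as features_mod
from . import io_ingest, preprocess, quality, sync
from .errors import PpgvalError, PreprocessError, SyncError
from .model import AccelRaw, ConditionWindow, IbiSeries
from .synthetic import SynthConfig, corrupt, simulate_accel, simulate_criterion

logger = logging.getLogger("ppgval")

__all__ = [
    "DeviceSpec",
    "StudyConfig",
    "CohortResult",
    "analyze_cohort",
    "run_pipeline",
    "load_config",
    "generate_study",
    "write_report",
]


@dataclass
class DeviceSpec:
    """One candidate device: its id, file dialect and path template.

    ``path`` may contain ``{participant}`` and ``{device}`` placeholders,
    resolved relative to the study's input directory. ``lag_override``
    (ms) bypasses automatic synchronization for this device.
    """

    device_id: str
    dialect: str = "generic"
    path: str = "{participant}/{device}.csv"
    lag_override: Optional[int] = None


@dataclass
class StudyConfig:
    participants: List[str]
    devices: List[DeviceSpec]
    criterion: DeviceSpec
    inputs_dir: str = "."
    conditions_file: str = "conditions.csv"
    output_dir: str = "out"
    seed: int = 0
    max_lag_s: float = 60.0
    grid_hz: float = 4.0
    range_low_ms: float = preprocess.RANGE_LOW_MS
    range_high_ms: float = preprocess.RANGE_HIGH_MS
    karlsson_start: float = preprocess.KARLSSON_START
    karlsson_step: float = preprocess.KARLSSON_STEP
    karlsson_cap: float = preprocess.KARLSSON_CAP
    hf_low_hz: float = features_mod.HF_LOW_HZ
    hf_high_hz: float = features_mod.HF_HIGH_HZ
    resample_hz: float = features_mod.RESAMPLE_HZ
    welch_nperseg: int = features_mod.WELCH_NPERSEG
    welch_overlap: float = features_mod.WELCH_OVERLAP
    exclude_poor: bool = False
    bonferroni_m: Optional[int] = None
    accel_path: Optional[str] = None  # template; None disables accel analysis
    accel_sample_rate_hz: float = 32.0
    accel_cutoff_hz: float = accel_mod.CUTOFF_HZ
    accel_order: int = accel_mod.FILTER_ORDER
    accel_digital_range: float = 65536.0
    accel_physical_range: float = 4.0
    make_plots: bool = False


@dataclass
class CohortResult:
    """All pipeline outputs as DataFrames plus run metadata."""

    features: pd.DataFrame
    quality: pd.DataFrame
    agreement: pd.DataFrame
    descriptives: pd.DataFrame
    lags: pd.DataFrame
    accel_means: pd.DataFrame
    thresholds: Dict[str, float]
    params: Dict[str, Any]

    def to_json_dict(self) -> Dict[str, Any]:
        def records(df: pd.DataFrame):
            return [
                {k: (None if isinstance(v, float) and np.isnan(v) else v)
                 for k, v in rec.items()}
                for rec in df.to_dict(orient="records")
            ]

        return {
            "features": records(self.features),
            "quality": records(self.quality),
            "agreement": records(self.agreement),
            "descriptives": records(self.descriptives),
            "lags": records(self.lags),
            "accel_means": records(self.accel_means),
            "thresholds": self.thresholds,
            "params": self.params,
        }


def analyze_cohort(
    streams: Dict[str, Dict[str, IbiSeries]],
    criterion_id: str,
    windows: Dict[str, List[ConditionWindow]],
    config: Optional[StudyConfig] = None,
    accel_data: Optional[Dict[str, AccelRaw]] = None,
    lag_overrides: Optional[Dict[str, int]] = None,
) -> CohortResult:
    """Run the full analysis on in-memory streams.

    ``streams`` maps participant -> device_id -> IbiSeries (the criterion
    must appear under ``criterion_id``; a device absent from a
    participant's dict is treated as a recording failure -> "missing").
    """
    cfg = config or StudyConfig(participants=[], devices=[], criterion=DeviceSpec("criterion"))
    all_devices = sorted(
        {d for per in streams.values() for d in per} - {criterion_id}
    )
    condition_names = sorted({w.name for ws in windows.values() for w in ws})
    feature_rows: List[dict] = []
    quality_records: List[quality.QualityRecord] = []
    lag_rows: List[dict] = []
    accel_rows: List[dict] = []
    thresholds: Dict[str, float] = {}
    hf_kwargs = dict(
        low_hz=cfg.hf_low_hz,
        high_hz=cfg.hf_high_hz,
        resample_hz=cfg.resample_hz,
        nperseg=cfg.welch_nperseg,
        overlap=cfg.welch_overlap,
    )

    for pid, per_device in streams.items():
        if pid not in windows:
            logger.warning("participant %s: no condition windows; skipped", pid)
            continue
        wins = windows[pid]
        criterion = per_device.get(criterion_id)
        if criterion is None or len(criterion) == 0:
            logger.warning("participant %s: criterion stream missing; skipped", pid)
            continue
        crit_seg = sync.segment(criterion, wins)
        try:
            threshold = preprocess.tune_threshold(
                crit_seg,
                start=cfg.karlsson_start,
                step=cfg.karlsson_step,
                cap=cfg.karlsson_cap,
                low=cfg.range_low_ms,
                high=cfg.range_high_ms,
            )
        except PreprocessError as exc:
            logger.warning("participant %s: %s; skipped", pid, exc)
            continue
        thresholds[pid] = threshold

        cleaned_by_device: Dict[str, Dict[str, preprocess.CleanResult]] = {}
        for dev_id in [criterion_id] + all_devices:
            series = per_device.get(dev_id)
            if dev_id == criterion_id:
                aligned = criterion
            elif series is None or len(series) == 0:
                # recording failure: every condition is missing
                for w in wins:
                    quality_records.append(
                        quality.QualityRecord(
                            pid, dev_id, w.name, quality.classify(0, 0, 0, has_data=False)
                        )
                    )
                    feature_rows.append(
                        dict(
                            participant_id=pid, device_id=dev_id, condition=w.name,
                            hr=np.nan, rmssd=np.nan, hf=np.nan, n_ibis=0,
                            quality="missing",
                        )
                    )
                continue
            else:
                override = (lag_overrides or {}).get(dev_id)
                if override is None:
                    try:
                        est = sync.estimate_lag(
                            series, criterion, max_lag_s=cfg.max_lag_s, grid_hz=cfg.grid_hz
                        )
                    except SyncError as exc:
                        logger.warning("participant %s device %s: %s", pid, dev_id, exc)
                        for w in wins:
                            quality_records.append(
                                quality.QualityRecord(
                                    pid, dev_id, w.name,
                                    quality.classify(0, 0, 0, has_data=False),
                                )
                            )
                            feature_rows.append(
                                dict(
                                    participant_id=pid, device_id=dev_id,
                                    condition=w.name, hr=np.nan, rmssd=np.nan,
                                    hf=np.nan, n_ibis=0, quality="missing",
                                )
                            )
                        continue
                    lag_rows.append(
                        dict(
                            participant_id=pid, device_id=dev_id,
                            lag_ms=est.lag_ms, correlation=est.correlation,
                            low_confidence=bool(est.low_confidence),
                        )
                    )
                    aligned = sync.apply_lag(series, est.lag_ms)
                else:
                    lag_rows.append(
                        dict(
                            participant_id=pid, device_id=dev_id,
                            lag_ms=int(override), correlation=np.nan,
                            low_confidence=False,
                        )
                    )
                    aligned = sync.apply_lag(series, override)

            seg = sync.segment(aligned, wins)
            cleaned: Dict[str, preprocess.CleanResult] = {}
            for name, segment_series in seg.segments.items():
                try:
                    cleaned[name] = preprocess.clean_segment(
                        segment_series, threshold,
                        low=cfg.range_low_ms, high=cfg.range_high_ms,
                    )
                except PreprocessError as exc:
                    logger.warning(
                        "participant %s device %s condition %s: %s", pid, dev_id, name, exc
                    )
                    cleaned[name] = preprocess.CleanResult(
                        segment_series.replace(), len(segment_series), threshold
                    )
            cleaned_by_device[dev_id] = cleaned

        crit_cleaned = cleaned_by_device.get(criterion_id, {})
        for dev_id, cleaned in cleaned_by_device.items():
            labels: Dict[str, str] = {}
            for name, result in cleaned.items():
                n_dev = len(result.series)
                n_crit = len(crit_cleaned[name].series) if name in crit_cleaned else 0
                if dev_id == criterion_id:
                    lbl = quality.classify(n_crit, n_crit, result.n_artifacts)
                else:
                    lbl = quality.classify(n_dev, n_crit, result.n_artifacts)
                labels[name] = lbl.label
                quality_records.append(
                    quality.QualityRecord(pid, dev_id, name, lbl, result.n_artifacts)
                )
            for row in features_mod.extract_features(
                pid, dev_id, cleaned, quality=labels, **hf_kwargs
            ):
                feature_rows.append(dataclasses.asdict(row))

        if accel_data and pid in accel_data:
            try:
                means = accel_mod.movement_summary(
                    accel_data[pid],
                    cfg.accel_sample_rate_hz,
                    wins,
                    cutoff_hz=cfg.accel_cutoff_hz,
                    order=cfg.accel_order,
                )
            except PpgvalError as exc:
                logger.warning("participant %s accel: %s", pid, exc)
            else:
                for name, g in means.items():
                    accel_rows.append(
                        dict(participant_id=pid, condition=name, mean_magnitude_g=g)
                    )

    features_df = pd.DataFrame(
        feature_rows,
        columns=[
            "participant_id", "device_id", "condition",
            "hr", "rmssd", "hf", "n_ibis", "quality",
        ],
    ).sort_values(["device_id", "condition", "participant_id"], ignore_index=True)
    quality_df = quality.quality_table(quality_records)
    agreement_df = (
        agreement_mod.agreement_table(
            features_df,
            criterion_id,
            exclude_poor=cfg.exclude_poor,
            family_size=cfg.bonferroni_m,
        )
        if len(features_df)
        else pd.DataFrame()
    )
    descriptives_df = _descriptives(features_df)
    accel_df = pd.DataFrame(
        accel_rows, columns=["participant_id", "condition", "mean_magnitude_g"]
    )
    if len(accel_df):
        accel_summary = (
            accel_df.groupby("condition", sort=True)["mean_magnitude_g"]
            .agg(["mean", "std", "count"])
            .reset_index()
            .rename(columns={"mean": "mean_g", "std": "sd_g", "count": "n"})
        )
    else:
        accel_summary = pd.DataFrame(columns=["condition", "mean_g", "sd_g", "n"])
    # paths are environment, not statistics: keep them out of the bundle so
    # reruns from different locations stay byte-identical
    params = {
        k: v
        for k, v in dataclasses.asdict(cfg).items()
        if k not in (
            "participants", "devices", "criterion",
            "inputs_dir", "output_dir", "conditions_file", "accel_path",
        )
    }
    params["criterion_id"] = criterion_id
    return CohortResult(
        features=features_df,
        quality=quality_df,
        agreement=agreement_df,
        descriptives=descriptives_df,
        lags=pd.DataFrame(
            lag_rows,
            columns=["participant_id", "device_id", "lag_ms", "correlation", "low_confidence"],
        ),
        accel_means=accel_summary,
        thresholds=thresholds,
        params=params,
    )


def _descriptives(features_df: pd.DataFrame) -> pd.DataFrame:
    """Mean, SD and SEM of each feature per device x condition."""
    rows = []
    if not len(features_df):
        return pd.DataFrame(
            columns=["device_id", "condition", "feature", "mean", "sd", "sem", "n"]
        )
    for (dev, cond), g in features_df.groupby(["device_id", "condition"], sort=True):
        for feat in ("hr", "rmssd", "hf"):
            vals = g[feat].dropna()
            n = len(vals)
            sd = float(vals.std(ddof=1)) if n > 1 else float("nan")
            rows.append(
                {
                    "device_id": dev,
                    "condition": cond,
                    "feature": feat,
                    "mean": float(vals.mean()) if n else float("nan"),
                    "sd": sd,
                    "sem": sd / np.sqrt(n) if n > 1 else float("nan"),
                    "n": n,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# file-based run


def load_config(path) -> StudyConfig:
    """Load a StudyConfig from YAML."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    devices = [DeviceSpec(**d) for d in raw.pop("devices")]
    criterion = DeviceSpec(**raw.pop("criterion"))
    return StudyConfig(devices=devices, criterion=criterion, **raw)


def _resolve(template: str, base: Path, participant: str, device: str) -> Path:
    return base / template.format(participant=participant, device=device)


def run_pipeline(config: StudyConfig) -> CohortResult:
    """Execute the full pipeline from files and write the report bundle."""
    base = Path(config.inputs_dir)
    windows = io_ingest.read_conditions_csv(base / config.conditions_file)
    streams: Dict[str, Dict[str, IbiSeries]] = {}
    accel_data: Dict[str, AccelRaw] = {}
    for pid in config.participants:
        per: Dict[str, IbiSeries] = {}
        spec = config.criterion
        path = _resolve(spec.path, base, pid, spec.device_id)
        if path.exists():
            per[spec.device_id] = io_ingest.read_ibi_csv(
                path, dialect=spec.dialect, device_id=spec.device_id, participant_id=pid
            )
        else:
            logger.warning("participant %s: criterion file %s not found", pid, path)
        for spec in config.devices:
            path = _resolve(spec.path, base, pid, spec.device_id)
            if path.exists():
                per[spec.device_id] = io_ingest.read_ibi_csv(
                    path, dialect=spec.dialect, device_id=spec.device_id,
                    participant_id=pid,
                )
        streams[pid] = per
        if config.accel_path:
            apath = _resolve(config.accel_path, base, pid, "accel")
            if apath.exists():
                accel_data[pid] = io_ingest.read_accel_csv(
                    apath, config.accel_digital_range, config.accel_physical_range
                )
    lag_overrides = {
        d.device_id: d.lag_override for d in config.devices if d.lag_override is not None
    }
    result = analyze_cohort(
        streams,
        config.criterion.device_id,
        windows,
        config=config,
        accel_data=accel_data or None,
        lag_overrides=lag_overrides or None,
    )
    write_report(result, Path(config.output_dir), make_plots=config.make_plots)
    return result


def write_report(result: CohortResult, out_dir: Path, make_plots: bool = False) -> None:
    """Write CSV/Markdown tables, the JSON statistics bundle, and plots.

    The tables are a pure rendering of the JSON bundle; every printed number
    is reproducible from it.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result.features.to_csv(out_dir / "features.csv", index=False)
    result.quality.to_csv(out_dir / "quality_table.csv", index=False)
    result.agreement.to_csv(out_dir / "agreement.csv", index=False)
    result.descriptives.to_csv(out_dir / "descriptives.csv", index=False)
    result.lags.to_csv(out_dir / "sync_lags.csv", index=False)
    result.accel_means.to_csv(out_dir / "accel_means.csv", index=False)
    with open(out_dir / "stats.json", "w") as fh:
        json.dump(result.to_json_dict(), fh, sort_keys=True, indent=1)
    with open(out_dir / "quality_table.md", "w") as fh:
        fh.write(render_quality_markdown(result.quality))
    with open(out_dir / "agreement.md", "w") as fh:
        fh.write(render_agreement_markdown(result.agreement))
    if make_plots and len(result.features):
        _plots(result, out_dir)


def render_quality_markdown(quality_df: pd.DataFrame) -> str:
    lines = [
        "| Device | Condition | Poor % | Missing % | Artifacts mean (SD) | Mean IBI detection rate % |",
        "| --- | --- | --- | --- | --- | --- |",
    ]
    for _, r in quality_df.iterrows():
        lines.append(
            f"| {r.device_id} | {r.condition} | {r.pct_poor:.1f} | {r.pct_missing:.1f} "
            f"| {r.artifacts_mean:.2f} ({r.artifacts_sd:.2f}) "
            f"| {r.mean_detection_rate:.2f} |"
        )
    return "\n".join(lines) + "\n"


def render_agreement_markdown(agreement_df: pd.DataFrame) -> str:
    lines = [
        "| Device | Condition | Feature | MAAPE (CI) | r [band] | Bias (LoA) | n |",
        "| --- | --- | --- | --- | --- | --- | --- |",
    ]
    for _, r in agreement_df.iterrows():
        lines.append(
            f"| {r.device_id} | {r.condition} | {r.feature} "
            f"| {r.maape:.2f} ({r.maape_ci_low:.2f}, {r.maape_ci_high:.2f}) "
            f"| {r.r:.2f} [{r.r_band}] "
            f"| {r.bias:.2f} ({r.loa_low:.2f}, {r.loa_high:.2f}) | {int(r.n)} |"
        )
    return "\n".join(lines) + "\n"


def _plots(result: CohortResult, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    crit = result.params.get("criterion_id", "criterion")
    feats = result.features
    for dev in sorted(set(feats["device_id"]) - {crit}):
        for feat in ("hr", "rmssd", "hf"):
            d = feats[feats["device_id"] == dev].set_index(["participant_id", "condition"])[feat]
            c = feats[feats["device_id"] == crit].set_index(["participant_id", "condition"])[feat]
            joined = pd.concat([d, c], axis=1, keys=["device", "criterion"]).dropna()
            if len(joined) < 3:
                continue
            fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
            ax1.scatter(joined["criterion"], joined["device"], s=12)
            lims = [joined.min().min(), joined.max().max()]
            ax1.plot(lims, lims, "k--", lw=0.8)
            ax1.set_xlabel(f"criterion {feat}")
            ax1.set_ylabel(f"{dev} {feat}")
            diffs = joined["device"] - joined["criterion"]
            means = (joined["device"] + joined["criterion"]) / 2
            bias = diffs.mean()
            sd = diffs.std(ddof=1)
            ax2.scatter(means, diffs, s=12)
            for yv, style in ((bias, "-"), (bias + 1.96 * sd, "--"), (bias - 1.96 * sd, "--")):
                ax2.axhline(yv, color="k", ls=style, lw=0.8)
            ax2.set_xlabel("mean of methods")
            ax2.set_ylabel("device - criterion")
            fig.suptitle(f"{dev} vs {crit}: {feat}")
            fig.tight_layout()
            fig.savefig(out_dir / f"{dev}_{feat}.png", dpi=100)
            plt.close(fig)


# ---------------------------------------------------------------------------
# synthetic study generation


DEFAULT_CONDITIONS: Tuple[Tuple[str, float], ...] = (
    ("sitting", 300.0),
    ("arithmetic", 180.0),
    ("recovery", 180.0),
    ("standing", 180.0),
    ("breathing", 180.0),
    ("neurotask", 600.0),
    ("walking", 180.0),
    ("biking", 180.0),
)

#: movement level (mean magnitude, g) per condition; sedentary conditions
#: around 0.01 g, walking clearly higher, biking intermediate
DEFAULT_MOVEMENT_G: Dict[str, float] = {
    "sitting": 0.01, "arithmetic": 0.02, "recovery": 0.01, "standing": 0.01,
    "breathing": 0.01, "neurotask": 0.01, "walking": 0.16, "biking": 0.08,
}


@dataclass
class DeviceProfile:
    """Corruption profile for one simulated device.

    ``missing_every`` plants recording failures: every k-th participant
    (0-based) has no file for this device at all.
    """

    device_id: str
    miss_rate: float = 0.0
    extra_rate: float = 0.0
    jitter_sd_ms: float = 0.0
    clock_offset_ms: int = 0
    dropout_condition: Optional[str] = None
    missing_every: Optional[int] = None


DEFAULT_PROFILES: Tuple[DeviceProfile, ...] = (
    DeviceProfile("good", clock_offset_ms=5000),
    DeviceProfile("lossy", miss_rate=0.08, jitter_sd_ms=8.0, clock_offset_ms=2000),
    DeviceProfile(
        "flaky", miss_rate=0.03, jitter_sd_ms=4.0, clock_offset_ms=-3000,
        dropout_condition="walking", missing_every=4,
    ),
)


def generate_study(
    out_dir,
    n_participants: int = 8,
    seed: int = 0,
    profiles: Sequence[DeviceProfile] = DEFAULT_PROFILES,
    conditions: Sequence[Tuple[str, float]] = DEFAULT_CONDITIONS,
    gap_s: float = 5.0,
    lead_s: float = 90.0,
    mean_ibi_ms: float = 900.0,
    rsa_amp_ms: float = 50.0,
    rsa_freq_hz: float = 0.25,
    noise_sd_ms: float = 25.0,
    accel: bool = True,
    accel_sample_rate_hz: float = 32.0,
) -> StudyConfig:
    """Write a complete synthetic study to ``out_dir`` and return its config.

    Emits, per participant: a criterion text export, one IBI CSV per device
    profile (plus a peaks CSV mirroring the criterion, exercising the
    peaks->IBI path), an accelerometer counts CSV; study-wide: the
    condition table and a ready-to-run ``study.yaml``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    participants = [f"p{i + 1:02d}" for i in range(n_participants)]
    total_s = lead_s + sum(d for _, d in conditions) + gap_s * len(conditions) + lead_s
    cond_rows = []
    for p_idx, pid in enumerate(participants):
        pdir = out_dir / pid
        pdir.mkdir(exist_ok=True)
        cfg = SynthConfig(
            seed=(seed * 100003 + p_idx * 97 + 1) % (2**31 - 1),
            duration_s=total_s,
            mean_ibi_ms=mean_ibi_ms,
            rsa_amp_ms=rsa_amp_ms,
            rsa_freq_hz=rsa_freq_hz,
            noise_sd_ms=noise_sd_ms,
        )
        criterion, _ = simulate_criterion(cfg, participant_id=pid)
        # criterion text export
        with open(pdir / "criterion.txt", "w") as fh:
            fh.write("# criterion IBI export\n")
            fh.write("timestamp\tibi\n")
            for t, v in zip(criterion.onsets, criterion.ibis):
                fh.write(f"{t}\t{v:.1f}\n")
        first_peak = criterion.onsets[0] - int(round(criterion.ibis[0]))
        pd.DataFrame(
            {"peak_time_ms": np.concatenate([[first_peak], criterion.onsets])}
        ).to_csv(pdir / "criterion_peaks.csv", index=False)

        t_cursor = lead_s * 1000.0
        wins = []
        for name, dur in conditions:
            start = int(round(t_cursor))
            end = int(round(t_cursor + dur * 1000.0))
            wins.append(ConditionWindow(name, start, end))
            cond_rows.append(
                dict(participant_id=pid, condition=name, start_ms=start, end_ms=end)
            )
            t_cursor = end + gap_s * 1000.0

        for d_idx, prof in enumerate(profiles):
            if prof.missing_every and p_idx % prof.missing_every == 0:
                continue  # planted recording failure
            dropouts: Tuple[Tuple[float, float], ...] = ()
            if prof.dropout_condition:
                w = next(w for w in wins if w.name == prof.dropout_condition)
                dropouts = ((w.start_ms + prof.clock_offset_ms,
                             w.end_ms + prof.clock_offset_ms),)
            dcfg = dataclasses.replace(
                cfg,
                seed=(cfg.seed + 13 * (d_idx + 1)) % (2**31 - 1),
                miss_rate=prof.miss_rate,
                extra_rate=prof.extra_rate,
                jitter_sd_ms=prof.jitter_sd_ms,
                clock_offset_ms=prof.clock_offset_ms,
                dropout_windows=dropouts,
            )
            device = corrupt(criterion, dcfg, device_id=prof.device_id)
            io_ingest.write_ibi_csv(device, pdir / f"{prof.device_id}.csv")

        if accel:
            raw = simulate_accel(
                wins, DEFAULT_MOVEMENT_G, accel_sample_rate_hz, cfg
            )
            pd.DataFrame(
                {"time_ms": raw.times, "x": raw.x.astype(np.int64),
                 "y": raw.y.astype(np.int64), "z": raw.z.astype(np.int64)}
            ).to_csv(pdir / "accel.csv", index=False)

    pd.DataFrame(cond_rows).to_csv(out_dir / "conditions.csv", index=False)
    config = StudyConfig(
        participants=participants,
        devices=[
            DeviceSpec(p.device_id, "generic", "{participant}/{device}.csv")
            for p in profiles
        ],
        criterion=DeviceSpec("criterion", "criterion_txt", "{participant}/criterion.txt"),
        inputs_dir=str(out_dir),
        conditions_file="conditions.csv",
        output_dir=str(out_dir / "out"),
        seed=seed,
        accel_path="{participant}/accel.csv" if accel else None,
        accel_sample_rate_hz=accel_sample_rate_hz,
    )
    import yaml

    cfg_dict = dataclasses.asdict(config)
    cfg_dict["devices"] = [
        {k: v for k, v in d.items() if v is not None} for d in cfg_dict["devices"]
    ]
    cfg_dict["criterion"] = {
        k: v for k, v in cfg_dict["criterion"].items() if v is not None
    }
    with open(out_dir / "study.yaml", "w") as fh:
        yaml.safe_dump(cfg_dict, fh, sort_keys=True)
    return config
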
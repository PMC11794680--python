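"""Signal-quality classification of segments and cohort quality summaries.

A segment is *missing* when the device recorded nothing for it (connection
failure, unretrievable data); *poor* when the device's beat count deviates
from the criterion's by more than 30%, or when artifacts exceed 30% of the
detected IBIs; *acceptable* otherwise. Both 30% comparisons are strict. A
segment with data but zero detected beats in the window is poor (a 100%
count deficit), not missing — "missing" is reserved for recording failure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List

import numpy as np
import pandas as pd

from .model import QualityLabel

__all__ = ["detection_rate", "classify", "QualityRecord", "quality_table"]

DEVIATION_THRESHOLD = 0.30
ARTIFACT_THRESHOLD = 0.30


def detection_rate(n_device: int, n_criterion: int) -> float:
    """Device beat count as a percentage of the criterion's. NaN when the
    criterion has no beats (undefined; propagates as missing)."""
    if n_criterion <= 0:
        return float("nan")
    return 100.0 * n_device / n_criterion


def classify(
    n_device: int,
    n_criterion: int,
    n_artifacts: int,
    has_data: bool = True,
) -> QualityLabel:
    """Label one participant x device x condition segment."""
    if not has_data:
        return QualityLabel("missing", float("nan"), float("nan"), "no recorded data")
    rate = detection_rate(n_device, n_criterion)
    artifact_pct = 100.0 * n_artifacts / n_device if n_device > 0 else float("nan")
    reasons = []
    if n_criterion > 0 and abs(n_device - n_criterion) / n_criterion > DEVIATION_THRESHOLD:
        reasons.append(
            f"IBI count deviates from criterion by more than "
            f"{DEVIATION_THRESHOLD:.0%} ({n_device} vs {n_criterion})"
        )
    if n_device > 0 and n_artifacts / n_device > ARTIFACT_THRESHOLD:
        reasons.append(
            f"artifacts exceed {ARTIFACT_THRESHOLD:.0%} of detected IBIs "
            f"({n_artifacts}/{n_device})"
        )
    if reasons:
        return QualityLabel("poor", rate, artifact_pct, "; ".join(reasons))
    return QualityLabel("acceptable", rate, artifact_pct, "")


@dataclass
class QualityRecord:
    """One classified segment, ready for cohort summarisation."""

    participant_id: str
    device_id: str
    condition: str
    label: QualityLabel
    n_artifacts: int = 0


def quality_table(records: Iterable[QualityRecord]) -> pd.DataFrame:
    """Cohort quality summary per device x condition.

    Columns: percent poor / missing / acceptable, mean and SD of artifact
    counts, and the mean IBI detection rate over non-missing segments.
    """
    rows = [
        {
            "device_id": r.device_id,
            "condition": r.condition,
            "label": r.label.label,
            "detection_rate": r.label.detection_rate,
            "n_artifacts": r.n_artifacts,
        }
        for r in records
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(
            columns=[
                "device_id", "condition", "n_segments", "pct_poor", "pct_missing",
                "pct_acceptable", "artifacts_mean", "artifacts_sd",
                "mean_detection_rate",
            ]
        )
    out = []
    for (dev, cond), g in df.groupby(["device_id", "condition"], sort=True):
        n = len(g)
        present = g[g["label"] != "missing"]
        out.append(
            {
                "device_id": dev,
                "condition": cond,
                "n_segments": n,
                "pct_poor": 100.0 * (g["label"] == "poor").sum() / n,
                "pct_missing": 100.0 * (g["label"] == "missing").sum() / n,
                "pct_acceptable": 100.0 * (g["label"] == "acceptable").sum() / n,
                "artifacts_mean": present["n_artifacts"].mean()
                if len(present) else float("nan"),
                "artifacts_sd": present["n_artifacts"].std(ddof=1)
                if len(present) > 1 else (0.0 if len(present) == 1 else float("nan")),
                "mean_detection_rate": present["detection_rate"].mean()
                if len(present) else float("nan"),
            }
        )
    return pd.DataFrame(out)
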
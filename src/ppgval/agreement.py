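"""Device-vs-criterion agreement statistics.

Three complementary views, computed per feature x device x condition on
participant-level paired values:

* **MAAPE** — mean arctangent absolute percentage error,
  ``100 * mean(arctan(|device - criterion| / |criterion|))`` with arctan in
  radians, so a perfect device scores 0 and the worst possible score is
  ``100 * pi/2 ~ 157.08``. Unlike plain MAPE it stays bounded when the
  criterion value is small, which matters for RMSSD.
* **Regression** — ordinary least squares of device on criterion (slope,
  intercept, Pearson r with a qualitative band, two-sided p for zero slope
  with Bonferroni adjustment across the comparison family, standard error).
* **Bland-Altman** — differences are device minus criterion; bias is their
  mean, limits of agreement are bias +/- 1.96 SD (sample SD, n-1), the bias
  CI uses the t distribution and each LoA CI the standard large-sample
  variance 3 sigma^2 / n.

RMSSD and HF values are natural-log transformed before regression and
Bland-Altman analysis (not before MAAPE), matching standard practice for
right-skewed HRV measures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import PpgvalError
from .model import AgreementStats

__all__ = [
    "maape",
    "maape_ci",
    "regress",
    "band_label",
    "bland_altman",
    "ln_transform",
    "adjust_p",
    "agreement_stats",
    "agreement_table",
    "LOG_FEATURES",
]

MAAPE_MAX = 100.0 * np.pi / 2  # asymptotic upper bound, percent

#: features log-transformed before regression / Bland-Altman
LOG_FEATURES = ("rmssd", "hf")

_BANDS = [
    (0.90, "very high"),
    (0.70, "high"),
    (0.50, "moderate"),
    (0.30, "low"),
    (0.00, "negligible"),
]


def _paired(device, criterion) -> Tuple[np.ndarray, np.ndarray]:
    d = np.asarray(device, dtype=float)
    c = np.asarray(criterion, dtype=float)
    if d.shape != c.shape:
        raise ValueError("device and criterion arrays must have the same length")
    return d, c


def maape(device, criterion) -> float:
    """Mean arctangent absolute percentage error, percent."""
    d, c = _paired(device, criterion)
    if len(d) == 0:
        raise PpgvalError("MAAPE needs at least one pair")
    if np.any(c == 0):
        raise PpgvalError("MAAPE undefined: criterion value of 0 encountered")
    return float(100.0 * np.mean(np.arctan(np.abs(d - c) / np.abs(c))))


def maape_ci(device, criterion, alpha: float = 0.05) -> Tuple[float, float]:
    """t-based confidence interval for MAAPE (percent scale)."""
    d, c = _paired(device, criterion)
    terms = 100.0 * np.arctan(np.abs(d - c) / np.abs(c))
    n = len(terms)
    if n < 2:
        return (float("nan"), float("nan"))
    m = terms.mean()
    half = stats.t.ppf(1 - alpha / 2, n - 1) * terms.std(ddof=1) / np.sqrt(n)
    return (float(m - half), float(m + half))


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r: float
    p: float
    stderr: float
    n: int


def regress(device, criterion) -> RegressionResult:
    """OLS of device on criterion with Pearson r and two-sided p for zero slope."""
    d, c = _paired(device, criterion)
    if len(d) < 3:
        raise PpgvalError("regression needs at least 3 pairs")
    if np.var(c) == 0:
        raise PpgvalError("regression undefined: criterion values have zero variance")
    res = stats.linregress(c, d)
    return RegressionResult(
        float(res.slope), float(res.intercept), float(res.rvalue),
        float(res.pvalue), float(res.stderr), len(d),
    )


def band_label(r: float) -> str:
    """Qualitative correlation band on |r|; boundaries go to the upper band."""
    a = abs(float(r))
    if a > 1:
        raise ValueError("|r| cannot exceed 1")
    for lo, name in _BANDS:
        if a >= lo:
            return name
    return "negligible"


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    ci_bias: Tuple[float, float]
    ci_loa_low: Tuple[float, float]
    ci_loa_high: Tuple[float, float]
    n: int


def bland_altman(device, criterion, alpha: float = 0.05) -> BlandAltman:
    """Bland-Altman bias and 95% limits of agreement with confidence intervals."""
    d, c = _paired(device, criterion)
    n = len(d)
    if n < 2:
        raise PpgvalError("Bland-Altman needs at least 2 pairs")
    diffs = d - c
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    z = stats.norm.ppf(1 - alpha / 2)
    loa_low, loa_high = bias - z * sd, bias + z * sd
    half_bias = stats.t.ppf(1 - alpha / 2, n - 1) * sd / np.sqrt(n)
    half_loa = z * sd * np.sqrt(3.0 / n)
    return BlandAltman(
        bias=bias,
        sd_diff=sd,
        loa_low=float(loa_low),
        loa_high=float(loa_high),
        ci_bias=(bias - float(half_bias), bias + float(half_bias)),
        ci_loa_low=(float(loa_low - half_loa), float(loa_low + half_loa)),
        ci_loa_high=(float(loa_high - half_loa), float(loa_high + half_loa)),
        n=n,
    )


def ln_transform(values, context: str = "") -> np.ndarray:
    """Natural log, elementwise; nonpositive values are a hard error."""
    v = np.asarray(values, dtype=float)
    bad = np.nonzero(v <= 0)[0]
    if len(bad):
        where = f" ({context})" if context else ""
        raise PpgvalError(
            f"log transform requires positive values; index {int(bad[0])} "
            f"is {v[bad[0]]!r}{where}"
        )
    return np.log(v)


def adjust_p(p_values, family_size: Optional[int] = None):
    """Bonferroni adjustment: p_adj = min(1, p * m)."""
    p = np.asarray(p_values, dtype=float)
    m = int(family_size) if family_size is not None else p.size
    if m < 1:
        raise ValueError("family size must be at least 1")
    out = np.minimum(1.0, p * m)
    return float(out) if np.isscalar(p_values) or p.ndim == 0 else out


def agreement_stats(
    device,
    criterion,
    log_transform: bool = False,
    family_size: int = 1,
    context: str = "",
) -> AgreementStats:
    """All three analyses on one cell of paired participant-level values.

    MAAPE uses the raw values; regression and Bland-Altman use the
    (optionally log-transformed) values.
    """
    d, c = _paired(device, criterion)
    ok = np.isfinite(d) & np.isfinite(c)
    d, c = d[ok], c[ok]
    m = maape(d, c)
    m_ci = maape_ci(d, c)
    if log_transform:
        dt, ct = ln_transform(d, context), ln_transform(c, context)
    else:
        dt, ct = d, c
    reg = regress(dt, ct)
    ba = bland_altman(dt, ct)
    return AgreementStats(
        maape=m,
        maape_ci=m_ci,
        slope=reg.slope,
        intercept=reg.intercept,
        r=reg.r,
        p_raw=reg.p,
        p_adjusted=adjust_p(reg.p, family_size),
        stderr=reg.stderr,
        r_band=band_label(reg.r),
        bias=ba.bias,
        sd_diff=ba.sd_diff,
        loa_low=ba.loa_low,
        loa_high=ba.loa_high,
        ci_bias=ba.ci_bias,
        ci_loa_low=ba.ci_loa_low,
        ci_loa_high=ba.ci_loa_high,
        n=len(d),
    )


def agreement_table(
    features: pd.DataFrame,
    criterion_id: str,
    feature_names: Sequence[str] = ("hr", "rmssd", "hf"),
    exclude_poor: bool = False,
    family_size: Optional[int] = None,
) -> pd.DataFrame:
    """Agreement statistics for every device x condition x feature cell.

    ``features`` holds one row per participant x device x condition with
    columns participant_id, device_id, condition, quality and the feature
    values. Pairs are participant-level and pairwise complete; cells with
    fewer than 3 complete pairs are skipped. Poor-quality segments are
    included by default (mirroring real-world use, where no criterion is
    available to screen them out); ``exclude_poor`` enables the sensitivity
    analysis.
    """
    df = features.copy()
    if exclude_poor:
        df = df[df["quality"] != "poor"]
    devices = sorted(set(df["device_id"]) - {criterion_id})
    conditions = sorted(set(df["condition"]))
    m = family_size if family_size is not None else len(devices) * len(conditions)
    crit = df[df["device_id"] == criterion_id].set_index(["participant_id", "condition"])
    rows = []
    for dev in devices:
        sub = df[df["device_id"] == dev].set_index(["participant_id", "condition"])
        for cond in conditions:
            for feat in feature_names:
                try:
                    dvals = sub.xs(cond, level="condition")[feat]
                    cvals = crit.xs(cond, level="condition")[feat]
                except KeyError:
                    continue
                joined = pd.concat([dvals, cvals], axis=1, keys=["d", "c"]).dropna()
                if len(joined) < 3:
                    continue
                try:
                    st = agreement_stats(
                        joined["d"].to_numpy(),
                        joined["c"].to_numpy(),
                        log_transform=feat in LOG_FEATURES,
                        family_size=m,
                        context=f"{dev}/{cond}/{feat}",
                    )
                except PpgvalError:
                    continue
                rows.append(
                    {
                        "device_id": dev,
                        "condition": cond,
                        "feature": feat,
                        "log_transformed": feat in LOG_FEATURES,
                        "maape": st.maape,
                        "maape_ci_low": st.maape_ci[0],
                        "maape_ci_high": st.maape_ci[1],
                        "slope": st.slope,
                        "intercept": st.intercept,
                        "r": st.r,
                        "r_band": st.r_band,
                        "p_raw": st.p_raw,
                        "p_adjusted": st.p_adjusted,
                        "stderr": st.stderr,
                        "bias": st.bias,
                        "sd_diff": st.sd_diff,
                        "loa_low": st.loa_low,
                        "loa_high": st.loa_high,
                        "ci_bias_low": st.ci_bias[0],
                        "ci_bias_high": st.ci_bias[1],
                        "ci_loa_low_low": st.ci_loa_low[0],
                        "ci_loa_low_high": st.ci_loa_low[1],
                        "ci_loa_high_low": st.ci_loa_high[0],
                        "ci_loa_high_high": st.ci_loa_high[1],
                        "n": st.n,
                    }
                )
    return pd.DataFrame(rows)
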
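"""Paired reproducibility and reliability statistics.

A feature measured on the same lesion under two conditions (gated vs
non-gated acquisition) is scored by:

* CoV — per-lesion coefficient of variation of the pair,
  ``100 * sd(a, b) / mean(a, b)`` with the sample (n-1) standard
  deviation, aggregated over lesions by the arithmetic mean;
* ICC(2,1) — single-measure, two-way random-effects, absolute-agreement
  intraclass correlation from the two-way ANOVA decomposition, with a
  95% CI by the McGraw & Wong F-based method.

Both metrics are mapped onto the conventional benchmark bands and
reported overall and stratified by lesion size (MTV < 3 vs >= 3 mL).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "cov_pair",
    "cov_feature",
    "icc_two_way_absolute",
    "classify_cov",
    "classify_icc",
    "stratify_by_mtv",
    "stability_report",
    "MTV_CUTOFF_ML",
]

#: lesion-size stratification cutoff (mL)
MTV_CUTOFF_ML = 3.0


def cov_pair(a: float, b: float) -> float:
    """Percent CoV of one measurement pair: 100*|a-b| / (sqrt(2)*mean)."""
    mean = (a + b) / 2.0
    if mean == 0:
        raise ValueError("pair mean is zero; CoV undefined")
    return float(100.0 * abs(a - b) / (math.sqrt(2.0) * abs(mean)))


def cov_feature(pairs: np.ndarray, aggregation: str = "mean") -> float:
    """Aggregate per-lesion CoVs for one feature (arithmetic mean by default,
    ``aggregation="median"`` as the robust alternative)."""
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array")
    if pairs.shape[0] < 3:
        raise ValueError(f"need at least 3 pairs, got {pairs.shape[0]}")
    covs = np.array([cov_pair(a, b) for a, b in pairs])
    if aggregation == "mean":
        return float(covs.mean())
    if aggregation == "median":
        return float(np.median(covs))
    raise ValueError(f"unknown aggregation {aggregation!r}")


def icc_two_way_absolute(
    table: np.ndarray, alpha: float = 0.05
) -> tuple[float, float, float]:
    """ICC(2,1) with its F-based 95% CI.

    Single-measure, two-way random-effects, absolute-agreement ICC from
    the ANOVA decomposition:
    ``(MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)``
    with MSR/MSC/MSE the row (subject), column (condition), and residual
    mean squares, k = 2 conditions. CI per McGraw & Wong (1996).

    An exactly zero-variance residual with identical columns is perfect
    agreement: returns (1, 1, 1).
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("table must be n x k with k >= 2")
    n, k = x.shape
    if n < 3:
        raise ValueError(f"need at least 3 subjects, got {n}")
    if np.allclose(x, x[:, [0]]):
        return 1.0, 1.0, 1.0

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((x - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = max(sse / ((n - 1) * (k - 1)), 0.0)

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return 1.0, 1.0, 1.0
    icc = (msr - mse) / denom

    if mse == 0:
        return float(icc), float(icc), float(icc)
    # Satterthwaite df for the A,1 confidence bounds
    a = k * icc / (n * (1.0 - icc)) if icc < 1 else np.inf
    b = 1.0 + k * icc * (n - 1) / (n * (1.0 - icc)) if icc < 1 else np.inf
    num = (a * msc + b * mse) ** 2
    den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = num / den
    f_u = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_l = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = (
        n * (msr - f_u * mse)
        / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
    )
    upper = (
        n * (f_l * msr - mse)
        / (k * msc + (k * n - k - n) * mse + n * f_l * msr)
    )
    return float(icc), float(lower), float(upper)


def classify_cov(cov_percent: float) -> str:
    """Benchmark band for a percent CoV: <5 excellent, 5-10 good,
    10-20 moderate, >20 poor (boundaries to the better band)."""
    if cov_percent < 5.0:
        return "excellent"
    if cov_percent <= 10.0:
        return "good"
    if cov_percent <= 20.0:
        return "moderate"
    return "poor"


def classify_icc(icc: float) -> str:
    """Benchmark band for an ICC: >0.90 excellent, 0.75-0.90 good,
    0.50-0.75 moderate, <0.50 poor (0.90 and 0.75 fall in 'good',
    0.50 in 'moderate'; negative estimates are 'poor')."""
    if icc > 0.90:
        return "excellent"
    if icc >= 0.75:
        return "good"
    if icc >= 0.50:
        return "moderate"
    return "poor"


def stratify_by_mtv(
    table: pd.DataFrame, cutoff: float = MTV_CUTOFF_ML, mtv_column: str = "mtv_ml"
) -> dict[str, pd.DataFrame]:
    """Partition a lesion table into small (MTV < cutoff) and large
    (MTV >= cutoff) strata."""
    if mtv_column not in table.columns:
        raise ValueError(f"table has no {mtv_column!r} column")
    return {
        "small": table[table[mtv_column] < cutoff],
        "large": table[table[mtv_column] >= cutoff],
    }


def stability_report(
    paired: pd.DataFrame,
    features: list[str] | None = None,
    aggregation: str = "mean",
) -> pd.DataFrame:
    """Per-feature, per-stratum CoV and ICC stability report.

    ``paired`` is a wide lesion table with one row per lesion, an
    ``mtv_ml`` column, and ``<feature>_gated`` / ``<feature>_nongated``
    value columns; missing values drop the lesion from that feature's
    analysis only. Returns rows of (feature, stratum, n, cov_percent,
    cov_class, icc, icc_ci_low, icc_ci_high, icc_class).
    """
    if features is None:
        features = sorted(
            {
                c[: -len("_gated")]
                for c in paired.columns
                if c.endswith("_gated") and f"{c[:-len('_gated')]}_nongated" in paired.columns
            }
        )
    strata = {"all": paired} | stratify_by_mtv(paired)
    rows = []
    for feat in features:
        cols = [f"{feat}_gated", f"{feat}_nongated"]
        for stratum, sub in strata.items():
            block = sub[cols].dropna()
            entry = {"feature": feat, "stratum": stratum, "n": len(block)}
            if len(block) >= 3:
                arr = block.to_numpy(dtype=float)
                means = arr.mean(axis=1)
                valid = means != 0
                cov = cov_feature(arr[valid], aggregation=aggregation)
                icc, lo, hi = icc_two_way_absolute(arr)
                entry |= {
                    "cov_percent": cov,
                    "cov_class": classify_cov(cov),
                    "icc": icc,
                    "icc_ci_low": lo,
                    "icc_ci_high": hi,
                    "icc_class": classify_icc(icc),
                }
            else:
                entry |= {
                    "cov_percent": np.nan,
                    "cov_class": None,
                    "icc": np.nan,
                    "icc_ci_low": np.nan,
                    "icc_ci_high": np.nan,
                    "icc_class": None,
                }
            rows.append(entry)
    return pd.DataFrame(rows)
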
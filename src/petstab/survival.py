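"""Prognostic evaluation: Cox proportional hazards, Harrell's c-index,
bootstrap c-index comparison, feature correlation, and the effective-test
Bonferroni correction.

Cox models are fitted by partial likelihood with the Breslow convention
for tied event times (statsmodels ``PHReg`` behind this surface).
Multiple-testing correction divides alpha by the effective number of
independent tests M_eff, obtained by collapsing clusters of collinear
features (|r| above a threshold) into single tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from statsmodels.duration.hazard_regression import PHReg

__all__ = [
    "CoxResult",
    "CindexComparison",
    "harrell_cindex",
    "univariable_cox",
    "multivariable_cox",
    "bootstrap_cindex_difference",
    "feature_correlation",
    "effective_tests",
    "bonferroni_alpha",
]


@dataclass(frozen=True)
class CoxResult:
    """Per-feature proportional-hazards estimate."""

    feature: str
    hr: float
    ci_low: float
    ci_high: float
    p_value: float
    n_used: int
    coef: float
    se: float
    converged: bool = True


@dataclass(frozen=True)
class CindexComparison:
    """Bootstrap comparison of two risk scores' concordance indices."""

    c_a: float
    c_b: float
    difference: float
    boot_ci_low: float
    boot_ci_high: float
    p_value: float
    n_boot: int
    n_redrawn: int = 0


def harrell_cindex(
    times: np.ndarray, events: np.ndarray, risk_scores: np.ndarray
) -> float:
    """Harrell's concordance index.

    Usable pairs are those where the shorter observed time is an event
    (a censored subject tied with an event counts as outliving it); pairs
    of events at identical times are not comparable. Concordant pairs
    score 1, tied risks 0.5.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    r = np.asarray(risk_scores, dtype=float)
    n = t.size
    concordant = 0.0
    comparable = 0
    for i in range(n):
        if e[i] != 1:
            continue
        shorter = (t > t[i]) | ((t == t[i]) & (e == 0))
        comparable += int(shorter.sum())
        concordant += float((r[i] > r[shorter]).sum()) + 0.5 * float(
            (r[i] == r[shorter]).sum()
        )
    if comparable == 0:
        raise ValueError("no comparable pairs; c-index undefined")
    return concordant / comparable


def _fit_cox(
    x: np.ndarray, times: np.ndarray, events: np.ndarray, names: list[str]
) -> list[CoxResult]:
    model = PHReg(times, x, status=events, ties="breslow")
    fit = model.fit()
    coefs = np.asarray(fit.params, dtype=float)
    ses = np.asarray(fit.bse, dtype=float)
    results = []
    for j, name in enumerate(names):
        coef, se = coefs[j], ses[j]
        # monotone partial likelihood: the estimate drifts without bound
        converged = bool(np.isfinite(se) and se < 1e3 and abs(coef) < 50)
        z = coef / se if se > 0 else np.inf
        p = 2.0 * stats.norm.sf(abs(z))
        # a monotone likelihood can push the Wald CI past float range
        delta = min(stats.norm.ppf(0.975) * se, 700.0 - abs(coef))
        results.append(
            CoxResult(
                feature=name,
                hr=float(np.exp(coef)),
                ci_low=float(np.exp(coef - delta)),
                ci_high=float(np.exp(coef + delta)),
                p_value=float(p),
                n_used=len(times),
                coef=float(coef),
                se=float(se),
                converged=converged,
            )
        )
    return results


def _drop_missing(arrs: list[np.ndarray]) -> list[np.ndarray]:
    ok = np.ones(arrs[0].shape[0], dtype=bool)
    for a in arrs:
        ok &= np.isfinite(a) if a.ndim == 1 else np.isfinite(a).all(axis=1)
    return [a[ok] for a in arrs]


def univariable_cox(
    feature: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    name: str = "feature",
) -> CoxResult:
    """Single-covariate Cox model (Breslow ties, Wald CI and p)."""
    f = np.asarray(feature, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    f, t, e = _drop_missing([f, t, e])
    if e.sum() < 2:
        raise ValueError("need at least 2 events")
    if np.ptp(f) == 0:
        raise ValueError(f"feature {name!r} is constant")
    return _fit_cox(f[:, None], t, e, [name])[0]


def multivariable_cox(
    features: pd.DataFrame, times: np.ndarray, events: np.ndarray
) -> list[CoxResult]:
    """Joint Cox model; per-feature HR, CI, and p."""
    x = features.to_numpy(dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    x, t, e = _drop_missing([x, t, e])
    if e.sum() < x.shape[1] + 1:
        raise ValueError("need more events than features")
    centered = x - x.mean(axis=0)
    rank = np.linalg.matrix_rank(centered)
    if rank < x.shape[1]:
        # name the columns involved in an exact linear dependence
        corr = np.corrcoef(centered, rowvar=False)
        pairs = [
            (features.columns[i], features.columns[j])
            for i in range(x.shape[1])
            for j in range(i + 1, x.shape[1])
            if abs(corr[i, j]) > 1.0 - 1e-10
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {pairs}")
    return _fit_cox(x, t, e, list(features.columns))


def bootstrap_cindex_difference(
    times: np.ndarray,
    events: np.ndarray,
    risk_a: np.ndarray,
    risk_b: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> CindexComparison:
    """Percentile bootstrap CI and p for the difference c_a - c_b.

    Patients are resampled with replacement; both c-indices are computed
    on the same resample. Degenerate resamples (no comparable pairs) are
    redrawn and counted. The two-sided p inverts the percentile position
    of zero in the bootstrap difference distribution.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    ra = np.asarray(risk_a, dtype=float)
    rb = np.asarray(risk_b, dtype=float)
    n = t.size
    if n < 10:
        raise ValueError(f"need at least 10 subjects, got {n}")
    c_a = harrell_cindex(t, e, ra)
    c_b = harrell_cindex(t, e, rb)
    rng = np.random.default_rng(seed)
    diffs = np.empty(n_boot)
    redrawn = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            try:
                da = harrell_cindex(t[idx], e[idx], ra[idx])
                db = harrell_cindex(t[idx], e[idx], rb[idx])
            except ValueError:
                redrawn += 1
                continue
            break
        diffs[b] = da - db
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    ties = float((diffs == 0).mean())
    p = 2.0 * min(
        float((diffs < 0).mean()) + 0.5 * ties,
        float((diffs > 0).mean()) + 0.5 * ties,
    )
    return CindexComparison(
        c_a=c_a,
        c_b=c_b,
        difference=c_a - c_b,
        boot_ci_low=float(lo),
        boot_ci_high=float(hi),
        p_value=float(min(p, 1.0)),
        n_boot=n_boot,
        n_redrawn=redrawn,
    )


def feature_correlation(features: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations with pairwise-complete observations;
    entries involving constant columns are NaN (flagged undefined)."""
    return features.corr(method="pearson", min_periods=3)


def effective_tests(correlation: pd.DataFrame, threshold: float = 0.8) -> int:
    """Effective number of independent tests M_eff.

    Features with |r| >= threshold are joined in a graph; M_eff is the
    number of connected components (collinear clusters count once).
    """
    r = np.asarray(correlation, dtype=float)
    if r.ndim != 2 or r.shape[0] != r.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(np.nan_to_num(r), np.nan_to_num(r.T), atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    adj = np.abs(np.nan_to_num(r)) >= threshold
    np.fill_diagonal(adj, False)
    n_comp, _ = connected_components(csr_matrix(adj), directed=False)
    return int(n_comp)


def bonferroni_alpha(alpha: float = 0.05, m_eff: int = 1) -> float:
    """Corrected significance threshold alpha / M_eff."""
    if m_eff < 1:
        raise ValueError("m_eff must be >= 1")
    return alpha / m_eff
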
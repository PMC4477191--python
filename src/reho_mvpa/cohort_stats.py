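"""Demographic/clinical group comparisons and the margin-symptom correlation.

Covers the usual case-control table: two-sample t-tests on age and symptom
scores (pooled-variance Student's t by default, computable from either raw
vectors or printed n/mean/SD summaries), a Pearson chi-square on the 2x2
sex table (no continuity correction), and Pearson/Spearman correlations
between each subject's SVM test margin and symptom-scale scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "TTestResult",
    "ChiSquareResult",
    "CorrelationResult",
    "two_sample_t",
    "chi_square_2x2",
    "margin_symptom_correlation",
]

LSAS_SCORES = ("lsas_total", "lsas_fear", "lsas_avoidance")


@dataclass
class GroupSummary:
    n: int
    mean: float
    sd: float  # sample SD (ddof=1)

    def __post_init__(self):
        if self.n < 2:
            raise ValueError(f"GroupSummary needs n >= 2, got n={self.n}")
        if self.sd < 0:
            raise ValueError(f"GroupSummary sd must be >= 0, got {self.sd}")

    @classmethod
    def from_values(cls, values) -> "GroupSummary":
        values = np.asarray(values, dtype=np.float64)
        if values.size < 2:
            raise ValueError(f"need at least 2 values, got {values.size}")
        return cls(n=int(values.size), mean=float(values.mean()),
                   sd=float(values.std(ddof=1)))


@dataclass
class TTestResult:
    t: float
    df: float
    p: float


@dataclass
class ChiSquareResult:
    chi2: float
    df: int
    p: float


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    method: str
    subset: str = ""
    score: str = ""


def _as_summary(x) -> GroupSummary:
    return x if isinstance(x, GroupSummary) else GroupSummary.from_values(x)


def two_sample_t(a, b, welch: bool = False) -> TTestResult:
    """Two-sample t-test from raw vectors or (n, mean, sd) summaries.

    Default is the classical pooled-variance Student's t; ``welch=True``
    uses the Welch-Satterthwaite unequal-variance form. Summaries and raw
    values give identical results because raw inputs are first reduced to
    their summaries.
    """
    a, b = _as_summary(a), _as_summary(b)
    diff = a.mean - b.mean
    if welch:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        se2 = va + vb
        df = se2**2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1)) if se2 > 0 else a.n + b.n - 2
    else:
        sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / (a.n + b.n - 2)
        se2 = sp2 * (1.0 / a.n + 1.0 / b.n)
        df = a.n + b.n - 2
    if se2 == 0:
        if diff == 0:
            return TTestResult(t=0.0, df=float(df), p=1.0)
        warnings.warn("zero pooled variance with unequal means; reporting p = 0")
        return TTestResult(t=float(np.sign(diff)) * np.inf, df=float(df), p=0.0)
    t = diff / np.sqrt(se2)
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=float(df), p=float(p))


def chi_square_2x2(table) -> ChiSquareResult:
    """Pearson chi-square on a 2x2 contingency table, without Yates
    continuity correction. All row and column margins must be positive."""
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {table.shape}")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        table = table.astype(np.float64)
        if np.any(table < 0) or np.any(table != np.round(table)):
            raise ValueError("table entries must be nonnegative integers")
        table = table.astype(np.int64)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("chi-square undefined: a table margin is zero")
    res = sps.chi2_contingency(table, correction=False)
    return ChiSquareResult(chi2=float(res.statistic), df=int(res.dof), p=float(res.pvalue))


def margin_symptom_correlation(
    cv_per_subject: pd.DataFrame,
    phenotype: pd.DataFrame,
    score: str = "lsas_total",
    subset: str = "patients",
    method: str = "pearson",
) -> CorrelationResult:
    """Correlate held-out test margins with a symptom score.

    ``subset`` is "patients" (rows with true_label +1) or "all";
    ``method`` is "pearson" or "spearman". Zero variance in either variable
    leaves r undefined (NaN) with a warning.
    """
    if score not in phenotype.columns:
        raise ValueError(f"score column {score!r} not in phenotype")
    merged = cv_per_subject.merge(phenotype[["subject_id", score]], on="subject_id")
    if subset == "patients":
        merged = merged[merged["true_label"] == 1]
    elif subset != "all":
        raise ValueError(f"subset must be 'patients' or 'all', got {subset!r}")
    merged = merged.dropna(subset=["test_margin", score])
    n = len(merged)
    if n < 3:
        raise ValueError(f"need at least 3 subjects with both values, got {n}")
    x = merged["test_margin"].to_numpy(dtype=np.float64)
    y = merged[score].to_numpy(dtype=np.float64)
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero variance: correlation undefined")
        return CorrelationResult(r=float("nan"), p=float("nan"), n=n,
                                 method=method, subset=subset, score=score)
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    return CorrelationResult(r=float(r), p=float(p), n=n, method=method,
                             subset=subset, score=score)
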
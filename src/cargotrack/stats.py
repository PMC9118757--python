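"""Condition-level nonparametric comparison and significance annotation.

Transport metrics pooled per condition are compared with the two-tailed
Wilcoxon–Mann–Whitney rank-sum test: exact enumeration when the sample
product is small and no ties are present, otherwise the normal approximation
with tie and continuity corrections. A variance-ratio F test is reported
alongside as a descriptive screen (it motivates the choice of a rank test;
it never switches the test). Stars follow the usual thresholds: * p < 0.05,
** p < 0.01, *** p < 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

__all__ = [
    "ComparisonResult",
    "mann_whitney_u",
    "variance_ratio_test",
    "stars_for_p",
    "compare_conditions",
]

#: p-value thresholds for ***, **, * (checked in this order).
_STAR_LEVELS = [(0.001, "***"), (0.01, "**"), (0.05, "*")]

#: Largest n_a * n_b for which the exact null distribution is enumerated.
_EXACT_LIMIT = 400


@dataclass(frozen=True)
class ComparisonResult:
    """One two-group comparison of a metric."""

    metric: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    u_statistic: float
    p_value: float
    f_statistic: float
    f_p_value: float
    stars: str


def stars_for_p(p: float) -> str:
    for threshold, stars in _STAR_LEVELS:
        if p < threshold:
            return stars
    return "ns"


def mann_whitney_u(sample_a, sample_b) -> tuple[float, float]:
    """Two-tailed Mann–Whitney U test; returns (U for sample_a, p).

    Exact enumeration is used when ``n_a * n_b <= 400`` and the pooled data
    are tie-free; otherwise the normal approximation with tie correction and
    continuity correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (a.size * b.size <= _EXACT_LIMIT and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def variance_ratio_test(sample_a, sample_b) -> tuple[float, float]:
    """Two-tailed F test of equal variances; returns (F, p).

    Descriptive screen only — it documents variance heterogeneity and is
    never used to switch the main test.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("variance test needs >= 2 values per sample")
    f = float(np.var(a, ddof=1) / np.var(b, ddof=1))
    dfa, dfb = a.size - 1, b.size - 1
    cdf = sps.f.cdf(f, dfa, dfb)
    p = float(2.0 * min(cdf, 1.0 - cdf))
    return f, min(p, 1.0)


def compare_conditions(
    table: pd.DataFrame,
    metric: str,
    group_column: str,
    control_label: str,
    holm: bool = False,
) -> pd.DataFrame:
    """Compare every non-control group against the control for one metric.

    Rows with NaN metric values are dropped per group (undefined transport
    parameters of non-moving trajectories). ``holm`` optionally applies a
    Holm step-down adjustment across the comparison rows (off by default, so
    raw per-comparison p-values are reported).
    """
    for col in (metric, group_column):
        if col not in table.columns:
            raise ValidationError(f"unknown column {col!r}")
    groups = {
        str(label): grp[metric].dropna().to_numpy()
        for label, grp in table.groupby(group_column, sort=True)
    }
    if control_label not in groups:
        raise ValidationError(f"control label {control_label!r} not present")
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups to compare")
    control = groups[control_label]

    results = []
    for label, sample in groups.items():
        if label == control_label:
            continue
        u, p = mann_whitney_u(sample, control)
        f, f_p = variance_ratio_test(sample, control)
        results.append(
            ComparisonResult(
                metric=metric,
                group_a=label,
                group_b=control_label,
                n_a=sample.size,
                n_b=control.size,
                median_a=float(np.median(sample)),
                median_b=float(np.median(control)),
                u_statistic=u,
                p_value=p,
                f_statistic=f,
                f_p_value=f_p,
                stars=stars_for_p(p),
            )
        )
    df = pd.DataFrame([r.__dict__ for r in results])
    if holm and len(df):
        order = np.argsort(df["p_value"].to_numpy())
        m = len(df)
        adjusted = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, min(1.0, (m - rank) * df["p_value"].iloc[idx]))
            adjusted[idx] = running
        df["p_value_holm"] = adjusted
        df["stars"] = [stars_for_p(p) for p in adjusted]
    return df
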
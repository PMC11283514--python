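"""Nonparametric condition comparisons: median/IQR summaries and the
Wilcoxon rank-sum (Mann-Whitney) test.

The gaze metrics are heavily non-normal, so groups are summarized by
median and interquartile range and compared with the two-sided rank-sum
test at alpha = 0.05. Missing values are dropped, never imputed. The unit
of analysis defaults to the recording (matching group sizes like 170/179
despite repeated measures per participant); a per-participant-mean
grouping is available for a more conservative analysis. No
multiple-testing correction is applied by default; a Holm option exists.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError
from .io import Condition

__all__ = [
    "GroupComparison",
    "median_iqr",
    "rank_sum_test",
    "compare_conditions",
    "compare_all",
    "format_comparison_table",
]


@dataclass(frozen=True)
class GroupComparison:
    """One Table-style comparison row for a single metric."""

    metric: str
    med_a: float
    iqr_a: tuple[float, float]
    med_b: float
    iqr_b: tuple[float, float]
    n_a: int
    n_b: int
    statistic: float  # rank sum of group a
    p_value: float
    significant: bool
    group_a: str = Condition.AI.value
    group_b: str = Condition.NO_AI.value


def _clean(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    return arr[np.isfinite(arr)]


def median_iqr(values: Sequence[float]) -> tuple[float, float, float]:
    """(median, q1, q3) with quartiles by linear interpolation.

    Non-finite values are dropped first; an empty remainder is an error
    (missing data is never imputed).
    """
    arr = _clean(values)
    if arr.size == 0:
        raise ValidationError("median_iqr of an empty (or all-missing) sequence")
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    return float(med), float(q1), float(q3)


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns ``(W, p)`` where ``W`` is the rank sum of the first group.
    The exact null distribution is used when the pooled sample is small
    (n_a + n_b <= 16) and tie-free; otherwise the normal approximation
    with tie and continuity corrections. Two groups with no ranking
    information at all (every pooled value identical) give p = 1.
    """
    a = _clean(a)
    b = _clean(b)
    if a.size == 0 or b.size == 0:
        raise ValidationError("rank_sum_test needs at least one value per group")
    pooled = np.concatenate([a, b])
    w_stat = float(sps.rankdata(pooled)[: a.size].sum())
    if np.all(pooled == pooled[0]):
        return w_stat, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size + b.size <= 16 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return w_stat, float(res.pvalue)


def compare_conditions(
    table: pd.DataFrame,
    metric: str,
    grouping: str = "per_recording",
    alpha: float = 0.05,
    group_a: str | Condition = Condition.AI,
    group_b: str | Condition = Condition.NO_AI,
) -> GroupComparison:
    """Compare one metric between the two conditions of a metric table.

    ``table`` is a metric table (see :func:`gazekit.aoi.metric_table`) or
    any DataFrame with ``condition``, ``participant_id`` and the metric
    column. ``grouping`` is ``per_recording`` (each recording is one
    observation) or ``per_participant_mean`` (metric averaged per
    participant within condition first).
    """
    if metric not in table.columns:
        raise ValidationError(f"metric {metric!r} not present in table")
    if grouping not in ("per_recording", "per_participant_mean"):
        raise ValidationError(f"unknown grouping {grouping!r}")
    group_a = Condition(group_a).value
    group_b = Condition(group_b).value
    for cond in (group_a, group_b):
        if not (table["condition"] == cond).any():
            raise ValidationError(f"condition {cond!r} absent from table")

    if grouping == "per_participant_mean":
        table = (
            table.groupby(["participant_id", "condition"], as_index=False)[metric].mean()
        )
    va = table.loc[table["condition"] == group_a, metric].to_numpy(dtype=float)
    vb = table.loc[table["condition"] == group_b, metric].to_numpy(dtype=float)
    va, vb = _clean(va), _clean(vb)
    if va.size == 0 or vb.size == 0:
        raise ValidationError(f"no finite values of {metric!r} in one condition")
    med_a, q1a, q3a = median_iqr(va)
    med_b, q1b, q3b = median_iqr(vb)
    stat, p = rank_sum_test(va, vb)
    return GroupComparison(
        metric=metric,
        med_a=med_a,
        iqr_a=(q1a, q3a),
        med_b=med_b,
        iqr_b=(q1b, q3b),
        n_a=int(va.size),
        n_b=int(vb.size),
        statistic=stat,
        p_value=p,
        significant=bool(p < alpha),
        group_a=group_a,
        group_b=group_b,
    )


def compare_all(
    table: pd.DataFrame,
    metrics: Sequence[str] | None = None,
    grouping: str = "per_recording",
    alpha: float = 0.05,
    holm: bool = False,
) -> pd.DataFrame:
    """Comparison rows for several metrics; optional Holm step-down correction."""
    if metrics is None:
        from .aoi import METRIC_NAMES

        metrics = [m for m in METRIC_NAMES if m in table.columns]
    comps = [compare_conditions(table, m, grouping=grouping, alpha=alpha) for m in metrics]
    df = pd.DataFrame(
        {
            "metric": [c.metric for c in comps],
            "median_a": [c.med_a for c in comps],
            "q1_a": [c.iqr_a[0] for c in comps],
            "q3_a": [c.iqr_a[1] for c in comps],
            "median_b": [c.med_b for c in comps],
            "q1_b": [c.iqr_b[0] for c in comps],
            "q3_b": [c.iqr_b[1] for c in comps],
            "n_a": [c.n_a for c in comps],
            "n_b": [c.n_b for c in comps],
            "statistic": [c.statistic for c in comps],
            "p_value": [c.p_value for c in comps],
        }
    )
    if holm:
        order = np.argsort(df["p_value"].to_numpy())
        m = len(df)
        adjusted = np.empty(m)
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, min(1.0, (m - rank) * df["p_value"].iloc[i]))
            adjusted[i] = running
        df["p_adjusted"] = adjusted
        df["significant"] = df["p_adjusted"] < alpha
    else:
        df["significant"] = df["p_value"] < alpha
    return df


def format_comparison_table(df: pd.DataFrame, group_a: str = "With AI", group_b: str = "Without AI") -> str:
    """Render a comparison DataFrame as a Markdown table (median [q1, q3])."""
    lines = [
        f"| Variable | {group_a} Med | {group_a} IQR | {group_b} Med | {group_b} IQR | p-val |",
        "|---|---|---|---|---|---|",
    ]
    for _, r in df.iterrows():
        star = "*" if r["significant"] else ""
        lines.append(
            f"| {r['metric']} | {r['median_a']:.2f} | [{r['q1_a']:.2f}, {r['q3_a']:.2f}] "
            f"| {r['median_b']:.2f} | [{r['q1_b']:.2f}, {r['q3_b']:.2f}] "
            f"| {r['p_value']:.4f}{star} |"
        )
    return "\n".join(lines)
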
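"""Summary and comparison statistics on per-sample log10 concentrations.

Concentrations are summarized per (sample type × stratum) as mean and SD
of the log10 values plus the share of samples with any detectable signal
(percent positive = share not left-censored).  Two-stratum contrasts are
mean differences from a Gaussian identity-link linear model with a single
group indicator — the model family whose symmetric Wald intervals match
how such mean differences with 95% CIs are conventionally reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

__all__ = [
    "GroupSummary",
    "GroupComparison",
    "summarize",
    "compare_groups",
    "feces_proximity_test",
    "significance_tier",
]


@dataclass(frozen=True)
class GroupSummary:
    sample_type: str
    group: str
    n: int
    mean: float
    sd: float
    percent_positive: float


@dataclass(frozen=True)
class GroupComparison:
    """Mean difference (group A minus group B) with its 95% CI."""

    sample_type: str
    contrast: str
    mean_difference: float
    ci_low: float
    ci_high: float
    p_value: float
    n_a: int
    n_b: int

    @property
    def significant(self) -> bool:
        """CI excludes zero (0.05 level)."""
        return not (self.ci_low <= 0.0 <= self.ci_high)


def significance_tier(p: float) -> str:
    """Annotation tier: '' / '*' (<0.05) / '**' (<0.01) / '***' (<0.001)."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def summarize(results: pd.DataFrame, grouping: str) -> pd.DataFrame:
    """Per-stratum mean/SD of log10 values and percent positive.

    Parameters
    ----------
    results
        One row per sample with at least ``sample_type``, ``log10_value``,
        ``censoring`` and the ``grouping`` column.
    grouping
        Stratifying column: ``"neighborhood"``, ``"category"``,
        ``"corporation"`` — or any column of ``results``.

    Returns
    -------
    DataFrame with columns ``sample_type``, ``group``, ``n``, ``mean``,
    ``sd``, ``percent_positive``.  A single-sample stratum reports sd 0.
    """
    if grouping not in results.columns:
        raise ValueError(f"grouping column {grouping!r} not in results")
    if results.empty:
        warnings.warn("no results to summarize; empty table returned")
        return pd.DataFrame(
            columns=["sample_type", "group", "n", "mean", "sd", "percent_positive"]
        )
    rows = []
    for (st, grp), sub in results.groupby(["sample_type", grouping], sort=True):
        vals = sub["log10_value"].to_numpy(dtype=float)
        detected = (sub["censoring"] != "left").to_numpy()
        rows.append(
            {
                "sample_type": st,
                "group": grp,
                "n": len(sub),
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                "percent_positive": 100.0 * float(np.mean(detected)),
            }
        )
    return pd.DataFrame(rows)


def compare_groups(
    results: pd.DataFrame,
    grouping: str,
    group_a: str,
    group_b: str,
    sample_type: Optional[str] = None,
    ci_multiplier: str = "normal",
) -> Optional[GroupComparison]:
    """Mean difference ``group_a - group_b`` for one sample type.

    Fits ``log10_value ~ 1 + indicator(group_a)`` by ordinary least
    squares (the Gaussian identity-link linear model); the indicator
    coefficient is exactly ``mean_A - mean_B`` and its model SE gives the
    95% CI (``1.96*SE`` by default; Student-t quantile with
    ``ci_multiplier="t"``).

    Returns ``None`` (comparison suppressed) when either stratum has
    fewer than two samples.
    """
    sub = results
    if sample_type is not None:
        sub = sub[sub["sample_type"] == sample_type]
    a = sub.loc[sub[grouping] == group_a, "log10_value"].to_numpy(dtype=float)
    b = sub.loc[sub[grouping] == group_b, "log10_value"].to_numpy(dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError(
            f"empty stratum in contrast {group_a!r} vs {group_b!r}"
        )
    if len(a) < 2 or len(b) < 2:
        warnings.warn(
            f"stratum with n<2 in contrast {group_a!r} vs {group_b!r}; "
            "comparison suppressed"
        )
        return None
    y = np.concatenate([a, b])
    x = sm.add_constant(
        np.concatenate([np.ones(len(a)), np.zeros(len(b))])
    )
    fit = sm.OLS(y, x).fit()
    delta = float(fit.params[1])
    se = float(fit.bse[1])
    if ci_multiplier == "normal":
        mult = 1.959963984540054  # Phi^{-1}(0.975)
    elif ci_multiplier == "t":
        mult = float(scipy.stats.t.ppf(0.975, df=len(y) - 2))
    else:
        raise ValueError("ci_multiplier must be 'normal' or 't'")
    return GroupComparison(
        sample_type=sample_type if sample_type is not None else "all",
        contrast=f"{group_a} - {group_b}",
        mean_difference=delta,
        ci_low=delta - mult * se,
        ci_high=delta + mult * se,
        p_value=float(fit.pvalues[1]),
        n_a=len(a),
        n_b=len(b),
    )


def compare_groups_table(
    results: pd.DataFrame,
    grouping: str,
    group_a: str,
    group_b: str,
    ci_multiplier: str = "normal",
) -> pd.DataFrame:
    """One contrast row per sample type present in ``results``."""
    rows = []
    for st in sorted(results["sample_type"].unique()):
        cmp = compare_groups(
            results,
            grouping,
            group_a,
            group_b,
            sample_type=st,
            ci_multiplier=ci_multiplier,
        )
        if cmp is None:
            continue
        rows.append(
            {
                "sample_type": st,
                "contrast": cmp.contrast,
                "mean_difference": cmp.mean_difference,
                "ci_low": cmp.ci_low,
                "ci_high": cmp.ci_high,
                "p_value": cmp.p_value,
                "significance": significance_tier(cmp.p_value),
                "n_a": cmp.n_a,
                "n_b": cmp.n_b,
            }
        )
    return pd.DataFrame(rows)


def feces_proximity_test(
    near: np.ndarray, far: np.ndarray
) -> Dict[str, float]:
    """Two-sample tests for soil contamination near vs. away from feces.

    Runs both a pooled-variance two-sample t-test and a Wilcoxon
    rank-sum (Mann-Whitney) test with tie correction on the log10
    concentrations, returning both statistics and two-sided p-values.
    """
    near = np.asarray(near, dtype=float)
    far = np.asarray(far, dtype=float)
    if len(near) == 0 or len(far) == 0:
        raise ValueError("both partitions must be non-empty")
    t_stat, t_p = scipy.stats.ttest_ind(near, far, equal_var=True)
    if np.array_equal(np.sort(near), np.sort(far)):
        # identical samples: the t statistic is 0/0; report no effect
        t_stat, t_p = 0.0, 1.0
    u_stat, u_p = scipy.stats.mannwhitneyu(
        near, far, alternative="two-sided"
    )
    return {
        "t_statistic": float(t_stat),
        "t_p_value": float(t_p),
        "rank_sum_statistic": float(u_stat),
        "rank_sum_p_value": float(u_p),
    }
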
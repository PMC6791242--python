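"""Group statistics for normalized viability summaries.

Confidence intervals are the classic t-based interval
``mean +/- t_{(1+level)/2, n-1} * sd / sqrt(n)`` on each group's own
(mean, SD, n); endpoints are reported to 2 decimals to match the
published tables. Group-vs-control comparisons support a pooled
two-sample t (df = 2n - 2; for two groups one-way ANOVA's F is exactly
t^2), Welch's t, or a one-sample t against the fixed 100% control.
Significance flags follow the usual convention: ``**`` for p < 0.01,
``*`` for p < 0.05, ``ns`` otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dataset import CONTROL, GroupSummary, ResponseGrid, StimulationCondition

__all__ = [
    "GroupComparison",
    "ImprovementSummary",
    "t_confidence_interval",
    "compare_to_control",
    "two_group_anova_p",
    "significance_flag",
    "grid_argmax",
    "improvement_summary",
    "comparison_table",
]


@dataclass(frozen=True)
class GroupComparison:
    """One condition's summary stats, 95% CI, p-value vs control and flag."""

    condition: StimulationCondition
    mean: float
    sd: float
    n: int
    ci_low: float
    ci_high: float
    p_value: float
    flag: str


@dataclass(frozen=True)
class ImprovementSummary:
    """Viability gains: best grid cell over the 100% control, and the
    optimized condition over the best grid cell (percentage points)."""

    best_condition: StimulationCondition
    best_mean: float
    improvement_over_control: float
    optimized_mean: float
    further_improvement: float


def t_confidence_interval(
    mean: float,
    sd: float,
    n: int,
    level: float = 0.95,
    decimals: int | None = 2,
) -> tuple[float, float]:
    """t-based confidence interval for a group mean from (mean, sd, n).

    Computed at full precision as ``mean +/- t * sd / sqrt(n)`` with n-1
    degrees of freedom, then rounded to ``decimals`` (pass ``None`` for
    unrounded endpoints).
    """
    if n < 2:
        raise ValueError(f"need n >= 2 for a confidence interval, got n={n}")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if not 0 < level < 1:
        raise ValueError("level must be in (0,1)")
    half = sps.t.ppf((1 + level) / 2, n - 1) * sd / np.sqrt(n)
    lo, hi = float(mean - half), float(mean + half)
    if decimals is not None:
        lo, hi = round(lo, decimals), round(hi, decimals)
    return lo, hi


def _pooled_t(m1, s1, n1, m2, s2, n2):
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
    se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    if se == 0:
        return (0.0 if m1 == m2 else np.inf * np.sign(m1 - m2)), df
    return (m1 - m2) / se, df


def _p_from_t(t, df) -> float:
    if np.isinf(t):
        return 0.0
    return float(2 * sps.t.sf(abs(t), df))


def significance_flag(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_to_control(
    summary: GroupSummary,
    control: GroupSummary | None = None,
    method: str = "pooled",
) -> GroupComparison:
    """Two-sided comparison of a treated group against the 100% control.

    ``pooled`` (default): two-sample t with pooled variance, df = n1+n2-2
    (equivalent to two-group one-way ANOVA). ``welch``: unequal-variance
    t. ``one_sample``: t of the group mean against the constant 100.
    """
    if summary.n_replicates < 2:
        raise ValueError("treated group needs n >= 2")
    if control is None:
        control = GroupSummary(CONTROL, 100.0, 0.0, summary.n_replicates)
    m1, s1, n1 = summary.mean_viability, summary.sd_viability, summary.n_replicates
    m0, s0, n0 = control.mean_viability, control.sd_viability, control.n_replicates

    if method == "pooled":
        t, df = _pooled_t(m1, s1, n1, m0, s0, n0)
        p = _p_from_t(t, df)
    elif method == "welch":
        t, p = sps.ttest_ind_from_stats(m1, s1, n1, m0, s0, n0, equal_var=False)
        p = float(p) if np.isfinite(p) else (1.0 if m1 == m0 else 0.0)
    elif method == "one_sample":
        if s0 > 0:
            warnings.warn(
                "one_sample method ignores the control group's nonzero SD",
                stacklevel=2,
            )
        if s1 == 0:
            p = 1.0 if m1 == m0 else 0.0
        else:
            t = (m1 - m0) / (s1 / np.sqrt(n1))
            p = _p_from_t(t, n1 - 1)
    else:
        raise ValueError(f"unknown method {method!r}")

    lo, hi = t_confidence_interval(m1, s1, n1)
    return GroupComparison(summary.condition, m1, s1, n1, lo, hi, p, significance_flag(p))


def two_group_anova_p(summary: GroupSummary, control: GroupSummary) -> float:
    """One-way ANOVA p for two groups from summary stats; F = t_pooled^2,
    so this equals the pooled-t p exactly."""
    t, df = _pooled_t(
        summary.mean_viability, summary.sd_viability, summary.n_replicates,
        control.mean_viability, control.sd_viability, control.n_replicates,
    )
    if np.isinf(t):
        return 0.0
    return float(sps.f.sf(t**2, 1, df))


def grid_argmax(grid: ResponseGrid) -> tuple[StimulationCondition, float]:
    """Condition with the largest mean viability; ties go to the
    lexicographically smallest (voltage, frequency, duration)."""
    cells = grid.summaries or ((grid.control,) if grid.control else ())
    if not cells:
        raise ValueError("grid is empty")
    best = max(cells, key=lambda s: (s.mean_viability, [-v for v in s.condition.as_array()]))
    return best.condition, best.mean_viability


def improvement_summary(grid: ResponseGrid, optimized: GroupSummary) -> ImprovementSummary:
    """Percentage-point gains of the best grid cell over the control and of
    the optimized group over the best grid cell, to 2 decimals."""
    cond, best_mean = grid_argmax(grid)
    return ImprovementSummary(
        best_condition=cond,
        best_mean=best_mean,
        improvement_over_control=round(best_mean - 100.0, 2),
        optimized_mean=optimized.mean_viability,
        further_improvement=round(optimized.mean_viability - best_mean, 2),
    )


def comparison_table(
    grid: ResponseGrid,
    method: str = "pooled",
    control_n: int | None = None,
) -> pd.DataFrame:
    """Per-cell comparison table mirroring the published layout:
    ``voltage_v,frequency_mhz,duration_min,mean_pct,sd_pct,n,ci_low,
    ci_high,p_value,flag``."""
    rows = []
    for s in grid.summaries:
        control = grid.control
        if control is None:
            control = GroupSummary(CONTROL, 100.0, 0.0, control_n or s.n_replicates)
        elif control_n is not None:
            control = GroupSummary(control.condition, control.mean_viability,
                                   control.sd_viability, control_n)
        c = compare_to_control(s, control, method=method)
        rows.append(
            {
                "voltage_v": s.condition.voltage,
                "frequency_mhz": s.condition.frequency,
                "duration_min": s.condition.duration,
                "mean_pct": c.mean,
                "sd_pct": c.sd,
                "n": c.n,
                "ci_low": c.ci_low,
                "ci_high": c.ci_high,
                "p_value": c.p_value,
                "flag": c.flag,
            }
        )
    return pd.DataFrame(rows)
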
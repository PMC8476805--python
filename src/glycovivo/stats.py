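"""Group statistics for scheduled time-course measurements.

The statistical policy applied to every endpoint: per-hour mean +/- SD
(n-1 denominator), one-way fixed-effects ANOVA across time points, and
Dunnett's many-to-one post-hoc comparisons of each hour against the 0-h
control with familywise error held at alpha = 0.05.  Comparisons are
two-sided.  Measurements are treated as independent; repeated measures per
animal are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TimeCourseTable",
    "AnovaResult",
    "DunnettResult",
    "summarize",
    "one_way_anova",
    "dunnett_vs_control",
]


@dataclass
class TimeCourseTable:
    """Per-subject measurements on a scheduled time grid.

    ``data`` has columns ``subject_id, hour, value``; ``variable`` and
    ``units`` tag what was measured.
    """

    data: pd.DataFrame
    variable: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        required = {"subject_id", "hour", "value"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")

    def groups(self) -> dict[float, np.ndarray]:
        return {
            float(h): g["value"].to_numpy(dtype=float)
            for h, g in self.data.groupby("hour", sort=True)
        }


@dataclass
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int
    eta_squared: float
    degenerate: bool = False


@dataclass
class DunnettResult:
    """Many-to-one comparisons of each hour against the control hour."""

    comparisons: pd.DataFrame  # hour, mean_diff, t, p_adjusted, significant, n
    anova: AnovaResult
    control_hour: float
    alpha: float
    n_control: int


def summarize(table: TimeCourseTable) -> pd.DataFrame:
    """Per-hour sample mean, SD (n-1 denominator) and n.

    Groups with a single value get ``sd = NaN`` and are flagged in the
    ``sd_defined`` column rather than raising; downstream tests require at
    least two values per group and will reject such tables themselves.
    """
    if table.data.empty:
        raise ValueError("empty table")
    g = table.data.groupby("hour", sort=True)["value"]
    out = g.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    out["sd_defined"] = out["n"] >= 2
    return out


def _anova_from_groups(groups: list[np.ndarray]) -> AnovaResult:
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    if k < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if (ns < 2).any():
        raise ValueError("every group needs at least 2 values")
    n_total = int(ns.sum())
    grand = np.concatenate(groups).mean()
    means = np.array([g.mean() for g in groups])
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            # all observations identical: no variance anywhere, no evidence
            return AnovaResult(0.0, 1.0, df_b, df_w, 0.0, degenerate=True)
        return AnovaResult(float("inf"), 0.0, df_b, df_w, 1.0)
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(F, df_b, df_w))
    eta = ss_between / (ss_between + ss_within)
    return AnovaResult(float(F), p, df_b, df_w, float(eta))


def one_way_anova(table: TimeCourseTable) -> AnovaResult:
    """Classical fixed-effects one-way ANOVA of value by hour."""
    return _anova_from_groups(list(table.groups().values()))


def dunnett_vs_control(
    table: TimeCourseTable,
    control_hour: float = 0.0,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = 0,
) -> DunnettResult:
    """Dunnett's test of every hour against the control hour.

    Two-sided many-to-one comparisons with familywise error control through
    the multivariate-t reference distribution (handles unbalanced group
    sizes).  ``rng`` seeds the numerical evaluation of the multivariate-t
    probabilities so adjusted p-values are reproducible.

    With a single comparison the adjusted p reduces to the ordinary pooled
    two-sided t-test p-value.
    """
    groups = table.groups()
    if float(control_hour) not in groups:
        raise ValueError(f"control hour {control_hour} not present in table")
    control = groups[float(control_hour)]
    hours = [h for h in sorted(groups) if h != float(control_hour)]
    if not hours:
        raise ValueError("no non-control groups to compare")
    samples = [groups[h] for h in hours]
    res = sps.dunnett(*samples, control=control, alternative="two-sided", rng=rng)
    pvalues = np.asarray(res.pvalue, dtype=float)
    if len(samples) == 1:
        # one comparison: the max-|t| distribution is exactly univariate t,
        # so evaluate it in closed form (= the pooled two-sided t-test)
        df = len(control) + len(samples[0]) - 2
        pvalues = 2 * sps.t.sf(np.abs(res.statistic), df)
    comparisons = pd.DataFrame(
        {
            "hour": hours,
            "mean_diff": [s.mean() - control.mean() for s in samples],
            "t": res.statistic,
            "p_adjusted": pvalues,
            "significant": pvalues < alpha,
            "n": [len(s) for s in samples],
        }
    )
    anova = _anova_from_groups([control, *samples])
    return DunnettResult(
        comparisons=comparisons,
        anova=anova,
        control_hour=float(control_hour),
        alpha=alpha,
        n_control=len(control),
    )
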
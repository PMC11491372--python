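"""Between-condition statistics on per-cell metric tables.

Cells are treated as independent observations pooled across experiments.
With two groups a classical (equal-variance) Student's t-test is reported;
with three or more, one-way ANOVA followed by Tukey HSD multiple
comparisons.  Group summaries use the standard error of the mean, matching
the plotting convention of the source data.  Significance stars follow the
usual thresholds (0.05, 0.01, 0.001, 0.0001).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def p_to_stars(p: float) -> str:
    for thr, stars in STAR_THRESHOLDS:
        if p < thr:
            return stars
    return "ns"


@dataclass
class GroupComparison:
    """One metric's between-group comparison."""

    metric: str
    #: per-group summary: label -> (n, mean, sem)
    groups: dict[str, tuple[int, float, float]]
    anova_F: Optional[float] = None
    anova_p: Optional[float] = None
    #: (label_a, label_b) -> Tukey-adjusted p; present when >= 3 groups
    tukey: dict[tuple[str, str], float] = field(default_factory=dict)
    ttest_t: Optional[float] = None
    ttest_p: Optional[float] = None

    def __post_init__(self) -> None:
        for p in list(self.tukey.values()) + [self.anova_p, self.ttest_p]:
            if p is not None and not 0.0 <= p <= 1.0 + 1e-12:
                raise ValueError(f"p-value {p} outside [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per comparison, with stars."""
        rows = []
        if self.anova_p is not None:
            rows.append(
                {"metric": self.metric, "comparison": "ANOVA",
                 "statistic": self.anova_F, "p": self.anova_p,
                 "p_adj": np.nan, "stars": p_to_stars(self.anova_p)}
            )
        if self.ttest_p is not None:
            rows.append(
                {"metric": self.metric, "comparison": "t-test",
                 "statistic": self.ttest_t, "p": self.ttest_p,
                 "p_adj": np.nan, "stars": p_to_stars(self.ttest_p)}
            )
        for (a, b), p in self.tukey.items():
            rows.append(
                {"metric": self.metric, "comparison": f"{a} vs {b}",
                 "statistic": np.nan, "p": np.nan, "p_adj": p,
                 "stars": p_to_stars(p)}
            )
        return pd.DataFrame(rows)


def compare_groups(
    records: pd.DataFrame, metric: str, grouping: str = "condition"
) -> GroupComparison:
    """Compare one metric between conditions.

    Requires at least two groups with at least two non-missing observations
    each.  Two identical groups give F = 0 (or t = 0) and p = 1 rather than
    an undefined statistic.
    """
    if metric not in records.columns:
        raise KeyError(f"metric {metric!r} not in table")
    df = records[[grouping, metric]].dropna()
    by_group = {str(k): g[metric].to_numpy(float) for k, g in df.groupby(grouping)}
    if len(by_group) < 2:
        raise ValueError(f"need >= 2 groups, got {len(by_group)}")
    for label, values in by_group.items():
        if values.size < 2:
            raise ValueError(f"group {label!r} has fewer than 2 observations")

    labels = sorted(by_group)
    samples = [by_group[k] for k in labels]
    summaries = {
        k: (int(v.size), float(v.mean()), float(stats.sem(v)) if v.size > 1 else 0.0)
        for k, v in by_group.items()
    }
    comp = GroupComparison(metric=metric, groups=summaries)

    all_values = np.concatenate(samples)
    if np.ptp(all_values) == 0:
        # identical data in every group: no effect, by convention p = 1
        comp.anova_F, comp.anova_p = 0.0, 1.0
        if len(labels) == 2:
            comp.ttest_t, comp.ttest_p = 0.0, 1.0
        comp.tukey = {
            (a, b): 1.0 for i, a in enumerate(labels) for b in labels[i + 1:]
        }
        return comp

    f, p = stats.f_oneway(*samples)
    comp.anova_F, comp.anova_p = float(f), float(p)

    if len(labels) == 2:
        t, tp = stats.ttest_ind(samples[0], samples[1], equal_var=True)
        comp.ttest_t, comp.ttest_p = float(t), float(tp)
    else:
        res = pairwise_tukeyhsd(
            endog=df[metric].to_numpy(float),
            groups=df[grouping].astype(str).to_numpy(),
            alpha=0.05,
        )
        uniques = [str(g) for g in res.groupsunique]
        pairs = [(a, b) for i, a in enumerate(uniques) for b in uniques[i + 1:]]
        comp.tukey = dict(zip(pairs, (float(p) for p in res.pvalues)))
    return comp


def comparisons_to_csv(
    comparisons: Sequence[GroupComparison], path: str | Path
) -> pd.DataFrame:
    """Write a stats CSV (metric, comparison, statistic, p, adjusted p, stars)."""
    frames = [c.to_frame() for c in comparisons]
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["metric", "comparison", "statistic", "p", "p_adj", "stars"]
    )
    out.to_csv(path, index=False)
    return out
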
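"""Distribution-level comparisons of windowed statistics.

Two designs from the study:

* a two-way ANOVA on globally rank-transformed window means, factors
  chromosome arm and population (or pair), without the interaction term
  (interactions are uninterpretable after rank transformation), followed
  by Tukey's HSD on each factor; and
* Kruskal-Wallis omnibus tests on 200-kb window values by group, with
  pairwise two-sided Wilcoxon rank-sum post-hoc tests reported only when
  the omnibus test is significant at 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd


@dataclass
class GroupComparison:
    statistic_name: str
    test: str
    statistic: float
    p: float
    factor_p: dict[str, float] = field(default_factory=dict)
    posthoc: pd.DataFrame | None = None


def rank_anova(
    values: np.ndarray,
    arm: np.ndarray,
    group: np.ndarray,
    statistic_name: str = "",
) -> GroupComparison:
    """Additive two-factor ANOVA on globally rank-transformed values.

    Raises when any arm x group cell is empty. Tukey HSD post-hoc tables
    (one per factor, on the ranks) are attached when the omnibus group
    effect has p < 0.05.
    """
    df = pd.DataFrame({"value": np.asarray(values, dtype=float),
                       "arm": arm, "group": group}).dropna()
    cells = df.groupby(["arm", "group"], observed=True).size()
    expected = [(a, g) for a in df["arm"].unique() for g in df["group"].unique()]
    missing = [c for c in expected if c not in cells.index]
    if missing:
        raise ValueError(f"empty arm x group cells: {missing}")
    if df["value"].nunique() <= 1:
        raise ValueError("no variation in values; rank ANOVA is degenerate")
    df["rank"] = stats.rankdata(df["value"])
    model = smf.ols("rank ~ C(arm) + C(group)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    factor_p = {
        "arm": float(table.loc["C(arm)", "PR(>F)"]),
        "group": float(table.loc["C(group)", "PR(>F)"]),
    }
    group_p = factor_p["group"]
    posthoc = None
    if min(factor_p.values()) < 0.05:
        tabs = []
        for factor in ("arm", "group"):
            if factor_p[factor] >= 0.05 or df[factor].nunique() < 2:
                continue
            res = pairwise_tukeyhsd(df["rank"], df[factor])
            t = pd.DataFrame(
                res.summary().data[1:], columns=res.summary().data[0]
            )
            t.insert(0, "factor", factor)
            tabs.append(t)
        posthoc = pd.concat(tabs, ignore_index=True) if tabs else None
    return GroupComparison(
        statistic_name=statistic_name,
        test="rank_anova",
        statistic=float(table.loc["C(group)", "F"]),
        p=group_p,
        factor_p=factor_p,
        posthoc=posthoc,
    )


def kruskal_windows(
    values_by_group: dict[str, np.ndarray], statistic_name: str = ""
) -> GroupComparison:
    """Kruskal-Wallis across groups of window values, Wilcoxon rank-sum
    post-hoc per pair when the omnibus p < 0.05. All-tied input gives
    p = 1."""
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    groups = {k: v[~np.isnan(v)] for k, v in groups.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(v) < 5 for v in groups.values()):
        raise ValueError("need at least five windows per group")
    allv = np.concatenate(list(groups.values()))
    if np.ptp(allv) == 0:
        return GroupComparison(statistic_name, "kruskal", 0.0, 1.0)
    H, p = stats.kruskal(*groups.values())
    posthoc = None
    if p < 0.05:
        rows = []
        for a, b in combinations(sorted(groups), 2):
            res = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
            rows.append({"group1": a, "group2": b, "U": res.statistic, "p": res.pvalue})
        posthoc = pd.DataFrame(rows)
    return GroupComparison(statistic_name, "kruskal", float(H), float(p), posthoc=posthoc)
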
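"""Inferential layer: one-sample tests against 1, one-way ANOVA across
networks, and the cognitive-vs-perceptual two-way ANOVA, all with explicit
Bonferroni families.

The two-way model treats network as nested within group (each network
belongs to exactly one group); the group main effect is the sequential
(type-I) F with group entered first, networks-within-group second, and
subjects as replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "UnityTestResult",
    "GroupAnovaResult",
    "test_vs_unity",
    "anova_networks",
    "anova_groups",
    "bonferroni",
    "DEFAULT_UNITY_FAMILY",
]

#: Default Bonferroni family for the against-1 tests: 6 networks × 3 indices.
DEFAULT_UNITY_FAMILY = 18


class StatsError(ValueError):
    pass


def bonferroni(p: float, family: int) -> float:
    if family < 1:
        raise StatsError("family size must be ≥ 1")
    return float(min(1.0, p * family))


@dataclass
class UnityTestResult:
    t: float
    p_raw: float
    p_corrected: float
    family: int
    degenerate: bool = False


@dataclass
class GroupAnovaResult:
    f: float
    p_raw: float
    p_corrected: float
    family: int
    df_num: int
    df_den: int


def test_vs_unity(values, family: int = DEFAULT_UNITY_FAMILY) -> UnityTestResult:
    """Two-sided one-sample t-test of a per-subject metric against 1."""
    v = np.asarray(values, dtype=float)
    if len(v) < 3:
        raise StatsError("need ≥ 3 values for a one-sample t-test")
    if v.std(ddof=1) == 0:
        if np.isclose(v.mean(), 1.0):
            return UnityTestResult(t=0.0, p_raw=1.0,
                                   p_corrected=1.0, family=family)
        return UnityTestResult(t=np.inf if v.mean() > 1 else -np.inf,
                               p_raw=0.0, p_corrected=0.0,
                               family=family, degenerate=True)
    t, p = sstats.ttest_1samp(v, popmean=1.0)
    return UnityTestResult(t=float(t), p_raw=float(p),
                           p_corrected=bonferroni(float(p), family),
                           family=family)


def _to_long(table: pd.DataFrame) -> pd.DataFrame:
    """Accept a wide subject×network table; return long (subject, network,
    value) with complete, balanced cells."""
    if table.isna().any().any():
        raise StatsError("metric table has missing cells")
    long = table.reset_index(names="subject").melt(
        id_vars="subject", var_name="network", value_name="value")
    return long


def anova_networks(table: pd.DataFrame) -> tuple[float, float]:
    """One-way ANOVA with network as factor and subjects as replicates.

    ``table``: wide DataFrame, rows = subjects, columns = networks.
    """
    if table.shape[1] < 2 or table.shape[0] < 2:
        raise StatsError("need ≥ 2 networks and ≥ 2 subjects")
    long = _to_long(table)
    groups = [g["value"].to_numpy() for _, g in long.groupby("network")]
    f, p = sstats.f_oneway(*groups)
    return float(f), float(p)


def anova_groups(table: pd.DataFrame, groups: dict[str, str],
                 family: int = 1) -> GroupAnovaResult:
    """Two-way ANOVA: factors group (2 levels) and network nested within
    group; the group main effect is reported, Bonferroni-corrected over
    ``family`` metrics.

    ``table``: wide subject×network DataFrame; ``groups``: network → group.
    """
    long = _to_long(table)
    long["group"] = long["network"].map(groups)
    if long["group"].isna().any():
        missing = sorted(set(long.loc[long["group"].isna(), "network"]))
        raise StatsError(f"networks without group assignment: {missing}")
    levels = long["group"].unique()
    if len(levels) != 2:
        raise StatsError("exactly two groups are required")
    for lv in levels:
        if (long["group"] == lv).sum() < 2:
            raise StatsError(f"group {lv!r} has fewer than 2 observations")
    model = smf.ols("value ~ C(group) + C(network)", data=long).fit()
    aov = sm.stats.anova_lm(model, typ=1)
    row = aov.loc["C(group)"]
    resid = aov.loc["Residual"]
    p = float(row["PR(>F)"])
    return GroupAnovaResult(
        f=float(row["F"]), p_raw=p, p_corrected=bonferroni(p, family),
        family=family, df_num=int(row["df"]), df_den=int(resid["df"]),
    )
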
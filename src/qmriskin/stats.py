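"""Supporting group statistics: t-tests, age correlations, severity ANOVA.

These mirror the study's statistical analysis: two-tailed unpaired Student
t-tests between groups (and between sexes), Pearson correlations of age
with each MR parameter within a group, and one-way ANOVA of each parameter
across the OI severity strata (mild / moderate / severe). No
multiple-testing correction is applied; p-values are reported raw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import PARAM_COLUMNS

__all__ = ["StatResult", "ttest_groups", "pearson_age_corr", "anova_severity"]


@dataclass(frozen=True)
class StatResult:
    test: str
    statistic: float
    df: float
    p_value: float
    effect: float  # mean difference (t-test) or R (correlation) or NaN
    note: str = ""

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def _column(table: pd.DataFrame, parameter: str) -> str:
    col = PARAM_COLUMNS.get(parameter, parameter)
    if col not in table.columns:
        raise KeyError(f"unknown parameter {parameter!r}")
    return col


def ttest_groups(table: pd.DataFrame, parameter: str, grouping: str = "group",
                 welch: bool = False) -> StatResult:
    """Two-tailed unpaired t-test of a parameter between two strata.

    Classical equal-variance Student t by default (``welch=True`` for the
    unequal-variance form). ``grouping`` names the column defining the two
    strata, e.g. ``"group"`` or ``"sex"``.
    """
    col = _column(table, parameter)
    levels = [lv for lv in pd.unique(table[grouping]) if pd.notna(lv)]
    if len(levels) != 2:
        raise ValueError(
            f"grouping {grouping!r} must have exactly 2 levels, got {levels}")
    a = table.loc[table[grouping] == levels[0], col].to_numpy(dtype=float)
    b = table.loc[table[grouping] == levels[1], col].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both strata need >= 2 observations")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    df = res.df if hasattr(res, "df") else len(a) + len(b) - 2
    return StatResult(
        test=f"ttest[{grouping}:{levels[0]} vs {levels[1]}]",
        statistic=float(res.statistic), df=float(df),
        p_value=float(res.pvalue), effect=float(a.mean() - b.mean()))


def pearson_age_corr(table: pd.DataFrame, parameter: str, group: str
                     ) -> StatResult:
    """Pearson correlation of age with a parameter within one group."""
    col = _column(table, parameter)
    sub = table[table["group"] == group]
    if len(sub) < 3:
        raise ValueError("need >= 3 subjects for a correlation")
    age = sub["age_years"].to_numpy(dtype=float)
    val = sub[col].to_numpy(dtype=float)
    if np.std(age) == 0 or np.std(val) == 0:
        raise ValueError("zero variance; correlation undefined")
    r, p = sps.pearsonr(age, val)
    return StatResult(test=f"pearson_age[{group}]", statistic=float(r),
                      df=float(len(sub) - 2), p_value=float(p),
                      effect=float(r))


def anova_severity(table: pd.DataFrame, parameter: str,
                   strata_column: str = "severity") -> StatResult:
    """One-way fixed-effects ANOVA across OI severity strata.

    Rows with stratum ``NA`` (the controls) are excluded. A fully
    degenerate input (zero within- and between-stratum variance) is
    flagged with NaN statistics rather than raising.
    """
    col = _column(table, parameter)
    sub = table[table[strata_column].isin(["mild", "moderate", "severe"])]
    groups = [g[col].to_numpy(dtype=float)
              for _, g in sub.groupby(strata_column)]
    if len(groups) < 2:
        raise ValueError("need >= 2 severity strata")
    if any(len(g) < 1 for g in groups):
        raise ValueError("every stratum needs >= 1 observation")
    allv = np.concatenate(groups)
    df1 = len(groups) - 1
    df2 = len(allv) - len(groups)
    if np.allclose(allv, allv[0]):
        return StatResult(test="anova[severity]", statistic=float("nan"),
                          df=float(df1), p_value=float("nan"),
                          effect=float("nan"),
                          note="degenerate: zero variance everywhere")
    f, p = sps.f_oneway(*groups)
    return StatResult(test="anova[severity]", statistic=float(f),
                      df=float(df1), p_value=float(p), effect=float("nan"),
                      note=f"df=({df1},{df2})")
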
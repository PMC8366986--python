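"""Descriptive statistics and two-group comparisons for a cohort table.

Continuous variables are summarized as mean ± SD, flags as n (%); group
comparisons use a t-test when both groups look normal (Shapiro–Wilk at
α = 0.05), a Mann–Whitney U test otherwise, and a chi-square test (no
continuity correction by default) for flags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["GroupComparison", "describe", "compare_groups", "table_one"]

NORMALITY_ALPHA = 0.05


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    kind: str  # "numeric" or "flag"
    overall: str
    group0: str  # endpoint-negative summary
    group1: str  # endpoint-positive summary
    test: str  # "t", "mann_whitney" or "chi2"
    statistic: float
    p_value: float


def _split(col: pd.Series, by: pd.Series) -> tuple[pd.Series, pd.Series]:
    by = by.astype(bool)
    g0, g1 = col[~by], col[by]
    for name, g in (("endpoint-negative", g0), ("endpoint-positive", g1)):
        if len(g) == 0:
            raise ValueError(f"empty group: {name}")
    return g0, g1


def _is_flag(col: pd.Series) -> bool:
    return col.dtype == bool or set(pd.unique(col.dropna())) <= {0, 1, True, False}


def _summary(col: pd.Series, flag: bool) -> str:
    if flag:
        n = int(col.sum())
        return f"{n} ({100.0 * n / len(col):.1f})"
    return f"{col.mean():.2f} ± {col.std(ddof=1) if len(col) > 1 else 0.0:.2f}"


def describe(col: pd.Series, by: pd.Series, name: str | None = None) -> dict[str, str]:
    """Per-group and overall summaries (mean ± SD, or n (%) for flags)."""
    g0, g1 = _split(col, by)
    flag = _is_flag(col)
    return {
        "variable": name or str(col.name),
        "kind": "flag" if flag else "numeric",
        "overall": _summary(col, flag),
        "group0": _summary(g0, flag),
        "group1": _summary(g1, flag),
    }


def _auto_test(g0: pd.Series, g1: pd.Series) -> str:
    normal = all(len(g) >= 3 and stats.shapiro(g).pvalue > NORMALITY_ALPHA
                 for g in (g0, g1))
    return "t" if normal else "mann_whitney"


def compare_groups(col: pd.Series, by: pd.Series, test: str = "auto",
                   name: str | None = None, *,
                   continuity_correction: bool = False) -> GroupComparison:
    """Two-sided two-group comparison of one cohort variable.

    ``test``: 'auto' (flags → chi2; else t if both groups pass a
    Shapiro–Wilk normality check, else Mann–Whitney), or an explicit
    't', 'mann_whitney' or 'chi2'.
    """
    g0, g1 = _split(col, by)
    flag = _is_flag(col)
    if test == "auto":
        test = "chi2" if flag else _auto_test(g0, g1)
    if test == "chi2":
        table = np.array([[int(g0.sum()), len(g0) - int(g0.sum())],
                          [int(g1.sum()), len(g1) - int(g1.sum())]])
        if (table.sum(axis=0) == 0).any():
            raise ValueError("degenerate 2x2 table: a column of the "
                             "contingency table is all zero")
        chi2, p, _, _ = stats.chi2_contingency(table, correction=continuity_correction)
        statistic = float(chi2)
    elif test == "t":
        statistic, p = stats.ttest_ind(g0, g1)
        statistic = float(statistic)
    elif test == "mann_whitney":
        method = "asymptotic" if min(len(g0), len(g1)) > 20 else "auto"
        statistic, p = stats.mannwhitneyu(g0, g1, alternative="two-sided",
                                          method=method)
        statistic = float(statistic)
    else:
        raise ValueError(f"unknown test {test!r}")
    d = describe(col, by, name)
    return GroupComparison(variable=d["variable"], kind=d["kind"],
                           overall=d["overall"], group0=d["group0"],
                           group1=d["group1"], test=test,
                           statistic=statistic, p_value=float(p))


def table_one(cohort: pd.DataFrame, endpoint: str = "balance_alteration",
              variables: list[str] | None = None) -> pd.DataFrame:
    """Descriptive comparison table for every covariate against the endpoint."""
    by = cohort[endpoint]
    if variables is None:
        variables = [c for c in cohort.columns if c not in (endpoint, "subject_id")]
    rows = []
    for var in variables:
        col = cohort[var]
        if col.dtype == object:  # e.g. sex as 'woman'/'man'
            col = (col == "woman")
            gc = compare_groups(col, by, name=f"{var} (women)")
        else:
            gc = compare_groups(col, by, name=var)
        rows.append({
            "variable": gc.variable, "kind": gc.kind, "overall": gc.overall,
            "no_balance_alteration": gc.group0, "balance_alteration": gc.group1,
            "test": gc.test, "p_value": gc.p_value,
        })
    return pd.DataFrame(rows)
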
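"""Mutational correlations among traits: Pearson correlations of line-mean
deviations from the control, with t-tests against zero and one-sided tests
against unity.

A significant correlation between, say, life-span and starvation-resistance
deviations across mutant lines indicates directional pleiotropy; a negative
one, antagonistic pleiotropy. Cross-sex genetic correlations significantly
below one indicate sex-specific mutational effects.
"""

from __future__ import annotations

import itertools
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats


class CorrelationTest(NamedTuple):
    se: float
    t: float
    p: float


def corr_test_vs_zero(r: float, df: int) -> CorrelationTest:
    """Test a Pearson correlation against zero.

    SE = sqrt((1 - r^2)/df), t = r/SE on ``df`` = n - 2 degrees of freedom,
    two-sided P.
    """
    if not abs(r) < 1:
        raise ValueError("|r| must be < 1 (the test is degenerate at the boundary)")
    if df < 1:
        raise ValueError("df must be at least 1")
    se = float(np.sqrt((1 - r * r) / df))
    t = r / se
    p = float(2 * stats.t.sf(abs(t), df))
    return CorrelationTest(se=se, t=float(t), p=p)


def corr_test_vs_one(r: float, df: int) -> float:
    """One-sided test that the population correlation is below one.

    Uses t = (1 - r)/SE(r) with SE = sqrt((1 - r^2)/df), the same standard
    error reported alongside the estimates. P is non-decreasing in r and
    tends to 0.5 as r approaches 1 from below (no evidence against unity at
    the boundary).
    """
    if r >= 1:
        raise ValueError("the test is degenerate for r >= 1")
    if df < 1:
        raise ValueError("df must be at least 1")
    se = np.sqrt((1 - r * r) / df)
    t = (1 - r) / se
    return float(stats.t.sf(t, df))


def mutational_correlations(
    deviations: pd.DataFrame,
    value_col: str = "value",
    min_pairs: int = 3,
) -> pd.DataFrame:
    """All pairwise trait correlations within each sex x age cell.

    ``deviations`` is a long table (line, sex, age_weeks, trait, value) of
    line-mean deviations from the control. Lines are matched pairwise-
    complete per trait pair (a trait scored on fewer lines only shrinks its
    own pairs), df = (lines with both traits) - 2. Cells with fewer than
    ``min_pairs`` complete lines are marked inestimable (NaN r, estimable
    False).
    """
    rows = []
    for (sex, age), sub in deviations.groupby(["sex", "age_weeks"]):
        wide = sub.pivot_table(index="line", columns="trait", values=value_col)
        for t1, t2 in itertools.combinations(sorted(wide.columns), 2):
            pair = wide[[t1, t2]].dropna()
            n = len(pair)
            row = {
                "trait_1": t1,
                "trait_2": t2,
                "sex": sex,
                "age_weeks": age,
                "n_lines": n,
                "r": np.nan,
                "se": np.nan,
                "df": max(n - 2, 0),
                "t": np.nan,
                "p_vs_zero": np.nan,
                "p_vs_one": np.nan,
                "estimable": False,
            }
            if n >= min_pairs:
                r = float(stats.pearsonr(pair[t1], pair[t2]).statistic)
                row["r"] = r
                row["estimable"] = True
                if abs(r) < 1:
                    test = corr_test_vs_zero(r, n - 2)
                    row.update(se=test.se, t=test.t, p_vs_zero=test.p)
                    row["p_vs_one"] = corr_test_vs_one(r, n - 2)
            rows.append(row)
    return pd.DataFrame(rows)


def correlation_matrix(
    results: pd.DataFrame, sex: str, age_weeks: int
) -> pd.DataFrame:
    """Square symmetric correlation matrix for one sex x age cell."""
    sub = results[(results["sex"] == sex) & (results["age_weeks"] == age_weeks)]
    traits = sorted(set(sub["trait_1"]) | set(sub["trait_2"]))
    mat = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)
    for _, row in sub.iterrows():
        mat.loc[row["trait_1"], row["trait_2"]] = row["r"]
        mat.loc[row["trait_2"], row["trait_1"]] = row["r"]
    return mat
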
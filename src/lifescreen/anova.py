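"""Mixed-model ANOVA engines, method-of-moments variance components,
mutational heritability, and the cross-sex genetic correlation.

Three layouts are covered, all on a quantitative trait of insertion lines
measured in replicate vials for both sexes:

* ``two_factor_mixed_anova`` — vial means, model Y = mu + L + S + LxS + e
  with Line random and Sex fixed (the sexes-pooled screen analysis);
* ``per_sex_anova`` — vial means of one sex, Y = mu + L + e;
* ``nested_individual_anova`` — individual flies with replicate vials nested
  within Line x Sex, Y = mu + L + S + LxS + R(LxS) + e (the secondary,
  mutant-versus-control analysis).

Variance components come from equating observed to expected mean squares.
For balanced designs the textbook closed forms are used; for unbalanced
designs the expectation coefficients are derived from the actual incidence
matrices (generalised Henderson Method III), which reduces to the same
closed forms when the design happens to be balanced.

Conventions: the mixed model is unrestricted (no sum-to-zero constraint on
the random interaction across the fixed factor), and every term's F uses
the error mean square as denominator by default — the convention of the
original screen analysis — with the denominator map configurable.
Negative component estimates are truncated to zero after estimation and
flagged.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from . import _design
from .data import SEXES


@dataclasses.dataclass
class VarianceComponents:
    """Variance components of the screen models, in days^2.

    ``sigma2_line`` and ``sigma2_line_sex`` come from the sexes-pooled
    two-factor model; the per-sex line components from the reduced one-way
    models; ``cov_fm`` is the cross-sex covariance of genetic (line) effects,
    estimable either as the covariance of per-line sex means or — the
    printed-table convention — as the pooled-model line component itself.
    """

    sigma2_line: float | None = None
    sigma2_line_sex: float | None = None
    sigma2_error: float | None = None
    sigma2_line_male: float | None = None
    sigma2_line_female: float | None = None
    cov_fm: float | None = None
    truncated: tuple[str, ...] = ()


class CorrelationEstimate(NamedTuple):
    value: float
    clamped: bool


def _f_and_p(table: pd.DataFrame, denominators: Mapping[str, str]) -> pd.DataFrame:
    table = table.copy()
    table["ms"] = table["ss"] / table["df"]
    ms = dict(zip(table["source"], table["ms"]))
    df = dict(zip(table["source"], table["df"]))
    F, P = [], []
    for _, row in table.iterrows():
        den = denominators.get(row["source"])
        if den is None or den not in ms or ms[den] <= 0 or row["df"] < 1:
            F.append(np.nan)
            P.append(np.nan)
        else:
            f = row["ms"] / ms[den]
            F.append(f)
            P.append(float(stats.f.sf(f, row["df"], df[den])))
    table["F"] = F
    table["P"] = P
    return table


def anova_from_mean_squares(
    mean_squares: Mapping[str, float],
    dfs: Mapping[str, float] | None = None,
    denominator: str = "Error",
) -> pd.DataFrame:
    """Assemble an ANOVA table from per-term mean squares.

    F for each term is its MS over the ``denominator`` term's MS (the
    error-denominator convention used throughout the screen); P values are
    attached when degrees of freedom are supplied.
    """
    if denominator not in mean_squares:
        raise ValueError(f"denominator term {denominator!r} not among mean squares")
    rows = []
    for source, ms in mean_squares.items():
        f = np.nan if source == denominator else ms / mean_squares[denominator]
        p = np.nan
        if dfs is not None and source != denominator and source in dfs and denominator in dfs:
            p = float(stats.f.sf(f, dfs[source], dfs[denominator]))
        rows.append(
            {
                "source": source,
                "df": np.nan if dfs is None else dfs.get(source, np.nan),
                "ms": ms,
                "F": f,
                "P": p,
            }
        )
    return pd.DataFrame(rows)


def _truncate(components: dict[str, float]) -> tuple[dict[str, float], tuple[str, ...]]:
    truncated = tuple(k for k, v in components.items() if v < 0)
    return {k: max(v, 0.0) for k, v in components.items()}, truncated


def _is_balanced(cells: pd.Series) -> bool:
    counts = cells.value_counts()
    return counts.nunique() == 1


def two_factor_mixed_anova(
    vials: pd.DataFrame,
    value_col: str = "mean_lifespan",
    denominators: Mapping[str, str] | None = None,
    force_general: bool = False,
) -> tuple[pd.DataFrame, VarianceComponents]:
    """Sexes-pooled two-factor mixed ANOVA of vial means.

    Sex is fitted before Line, Line before the interaction (sequential SS;
    identical to the orthogonal decomposition when the design is balanced).
    Returns the ANOVA table and method-of-moments components
    (sigma2_line, sigma2_line_sex, sigma2_error).
    """
    lines = vials["line"].unique()
    sexes = vials["sex"].unique()
    if len(lines) < 2:
        raise ValueError("two-factor ANOVA needs at least two lines")
    if set(sexes) != set(SEXES):
        raise ValueError(
            "both sexes must be present; use per_sex_anova for a single sex"
        )
    if denominators is None:
        denominators = {"Sex": "Error", "Line": "Error", "Line×Sex": "Error"}
    y = vials[value_col].to_numpy(dtype=float)
    line = vials["line"].to_numpy(dtype=object)
    sex = vials["sex"].to_numpy(dtype=object)
    cell = vials["line"].astype(str) + "⨯" + vials["sex"].astype(str)

    balanced = (
        not force_general
        and _is_balanced(cell)
        and cell.nunique() == 2 * len(lines)
    )
    if balanced:
        r = int(len(vials) / (2 * len(lines)))
        grand = y.mean()
        df = pd.DataFrame({"y": y, "line": line, "sex": sex})
        m_l = df.groupby("line")["y"].mean()
        m_s = df.groupby("sex")["y"].mean()
        m_ls = df.groupby(["line", "sex"])["y"].mean()
        ss_s = len(lines) * r * float(((m_s - grand) ** 2).sum())
        ss_l = 2 * r * float(((m_l - grand) ** 2).sum())
        inter = m_ls - m_l.reindex(m_ls.index.get_level_values(0)).to_numpy() \
            - m_s.reindex(m_ls.index.get_level_values(1)).to_numpy() + grand
        ss_ls = r * float((inter ** 2).sum())
        fitted = m_ls.loc[list(zip(line, sex))].to_numpy()
        ss_e = float(((y - fitted) ** 2).sum())
        table = pd.DataFrame(
            {
                "source": ["Sex", "Line", "Line×Sex", "Error"],
                "df": [1, len(lines) - 1, len(lines) - 1, len(y) - 2 * len(lines)],
                "ss": [ss_s, ss_l, ss_ls, ss_e],
            }
        )
        coef_ls_in_ls = r * (len(lines) - 1)        # tr coefficient of sigma2_LS in SS_LS
        coef_ls_in_l = r * (len(lines) - 1)         # of sigma2_LS in SS_L (unrestricted)
        coef_l_in_l = 2 * r * (len(lines) - 1)      # of sigma2_L in SS_L
    else:
        blocks = [
            ("Intercept", np.ones((len(y), 1))),
            ("Sex", _design.dummies(sex)),
            ("Line", _design.dummies(line)),
            ("Line×Sex", _design.dummies(cell)),
        ]
        seq, bases = _design.sequential_ss(y, blocks)
        table = seq[seq["source"] != "Intercept"].reset_index(drop=True)
        Z_l = _design.dummies(line)
        Z_ls = _design.dummies(cell)
        coef_l_in_l = _design.trace_coefficient(bases[1], bases[2], Z_l)
        coef_ls_in_l = _design.trace_coefficient(bases[1], bases[2], Z_ls)
        coef_ls_in_ls = _design.trace_coefficient(bases[2], bases[3], Z_ls)

    table = _f_and_p(table, denominators)
    ss = dict(zip(table["source"], table["ss"]))
    df = dict(zip(table["source"], table["df"]))
    if df["Error"] < 1:
        raise ValueError("no residual degrees of freedom for the error term")
    s2_e = ss["Error"] / df["Error"]
    s2_ls = (ss["Line×Sex"] - df["Line×Sex"] * s2_e) / coef_ls_in_ls
    s2_l = (ss["Line"] - df["Line"] * s2_e - coef_ls_in_l * s2_ls) / coef_l_in_l
    comps, truncated = _truncate(
        {"sigma2_line": s2_l, "sigma2_line_sex": s2_ls, "sigma2_error": s2_e}
    )
    vc = VarianceComponents(
        sigma2_line=comps["sigma2_line"],
        sigma2_line_sex=comps["sigma2_line_sex"],
        sigma2_error=comps["sigma2_error"],
        truncated=truncated,
    )
    return table, vc


def per_sex_anova(
    vials: pd.DataFrame,
    sex: str,
    value_col: str = "mean_lifespan",
) -> tuple[pd.DataFrame, VarianceComponents]:
    """One-way ANOVA of a single sex's vial means, Y = mu + L + e.

    The line component is (MS_L - MS_E)/c with c the design-derived
    replication coefficient: c = r for r vials per line, and
    (N - sum n_i^2 / N)/(a-1) in general.
    """
    if sex not in SEXES:
        raise ValueError(f"sex must be one of {SEXES}, got {sex!r}")
    sub = vials[vials["sex"] == sex]
    lines = sub["line"].unique()
    if len(lines) < 2:
        raise ValueError("per-sex ANOVA needs at least two lines")
    y = sub[value_col].to_numpy(dtype=float)
    n = len(y)
    counts = sub.groupby("line")[value_col].count()
    means = sub.groupby("line")[value_col].mean()
    grand = y.mean()
    ss_l = float((counts * (means - grand) ** 2).sum())
    fitted = means.loc[sub["line"]].to_numpy()
    ss_e = float(((y - fitted) ** 2).sum())
    df_l = len(lines) - 1
    df_e = n - len(lines)
    if df_e < 1:
        raise ValueError("no residual degrees of freedom (one vial per line)")
    table = _f_and_p(
        pd.DataFrame({"source": ["Line", "Error"], "df": [df_l, df_e], "ss": [ss_l, ss_e]}),
        {"Line": "Error"},
    )
    ms_l = ss_l / df_l
    ms_e = ss_e / df_e
    c = (n - float((counts**2).sum()) / n) / df_l
    comps, truncated = _truncate({"line": (ms_l - ms_e) / c, "error": ms_e})
    field = "sigma2_line_male" if sex == "male" else "sigma2_line_female"
    vc = VarianceComponents(sigma2_error=comps["error"], truncated=truncated)
    setattr(vc, field, comps["line"])
    return table, vc


def nested_individual_anova(
    records: pd.DataFrame,
    value_col: str = "death_age",
    denominators: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Individual-level ANOVA with replicate vials nested in Line x Sex.

    Model Y = mu + L + S + LxS + R(LxS) + e. Line, Sex and the interaction
    are tested over the replicate-vial stratum (the appropriate denominator
    when vials are random); the vial stratum over the within-vial error.
    Raises if there is no within-vial replication anywhere.
    """
    if denominators is None:
        denominators = {
            "Sex": "Replicate(Line×Sex)",
            "Line": "Replicate(Line×Sex)",
            "Line×Sex": "Replicate(Line×Sex)",
            "Replicate(Line×Sex)": "Error",
        }
    y = records[value_col].to_numpy(dtype=float)
    line = records["line"].astype(str)
    sex = records["sex"].astype(str)
    cell = line + "⨯" + sex
    vial = cell + "⨯" + records["vial"].astype(str)
    if vial.value_counts().max() < 2:
        raise ValueError(
            "within-vial error is inestimable: every vial holds a single fly"
        )
    blocks = [
        ("Intercept", np.ones((len(y), 1))),
        ("Sex", _design.dummies(sex)),
        ("Line", _design.dummies(line)),
        ("Line×Sex", _design.dummies(cell)),
        ("Replicate(Line×Sex)", _design.dummies(vial)),
    ]
    seq, _ = _design.sequential_ss(y, blocks)
    table = seq[seq["source"] != "Intercept"].reset_index(drop=True)
    return _f_and_p(table, denominators)


def line_sex_mean_covariance(
    vials: pd.DataFrame, value_col: str = "mean_lifespan"
) -> float:
    """Cross-sex covariance of per-line means (an estimate of cov_FM).

    Because male and female flies sit in different vials, measurement errors
    of the two sex means are independent and their covariance across lines
    estimates the genetic covariance directly. Lines missing either sex are
    dropped.
    """
    means = vials.pivot_table(index="line", columns="sex", values=value_col, aggfunc="mean")
    means = means.dropna(subset=list(SEXES))
    if len(means) < 2:
        raise ValueError("need at least two lines with both sexes")
    return float(np.cov(means["male"], means["female"], ddof=1)[0, 1])


def heritability(
    vc: VarianceComponents | float,
    sigma2_line_sex: float | None = None,
    sigma2_error: float | None = None,
) -> float:
    """Broad-sense mutational heritability.

    H^2 = (sigma2_L + sigma2_LS) / (sigma2_L + sigma2_LS + sigma2_e): the
    fraction of phenotypic variance among vial means attributable to line
    and line-by-sex effects. Accepts a VarianceComponents or the three
    components positionally.
    """
    if isinstance(vc, VarianceComponents):
        l, ls, e = vc.sigma2_line, vc.sigma2_line_sex, vc.sigma2_error
    else:
        l, ls, e = vc, sigma2_line_sex, sigma2_error
    if l is None or ls is None or e is None:
        raise ValueError("all three components are required")
    if min(l, ls, e) < 0:
        raise ValueError("components must be non-negative")
    total = l + ls + e
    if total == 0:
        raise ValueError("heritability is undefined when all components are zero")
    return (l + ls) / total


def cross_sex_genetic_correlation(
    vc: VarianceComponents, clamp: bool = True
) -> CorrelationEstimate:
    """Cross-sex genetic correlation r_MF = cov_FM / (sigma_LM sigma_LF).

    The numerator is ``vc.cov_fm`` when supplied; otherwise the sexes-pooled
    line component stands in for the cross-sex covariance (the convention of
    the screen's published component tables). The denominator is the product
    of the per-sex line standard deviations. The estimate is clamped to
    [-1, 1] with a flag, since component-based ratios can stray outside.
    """
    m, f = vc.sigma2_line_male, vc.sigma2_line_female
    if not m or not f or m <= 0 or f <= 0:
        raise ValueError("per-sex line components must be positive")
    num = vc.cov_fm if vc.cov_fm is not None else vc.sigma2_line
    if num is None:
        raise ValueError("need cov_fm or the pooled line component as numerator")
    r = num / float(np.sqrt(m * f))
    clamped = False
    if clamp and abs(r) > 1:
        r, clamped = float(np.sign(r)), True
    return CorrelationEstimate(float(r), clamped)
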
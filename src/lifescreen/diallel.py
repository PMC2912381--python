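"""Half-diallel combining-ability analysis (Griffing Method 4, Model 1).

All pairwise crosses among n homozygous parent lines, without selfs or
reciprocals, yield n(n-1)/2 double-heterozygote genotypes. The general
combining ability (GCA) of a parent is its average dominance effect across
crosses; the specific combining ability (SCA) of a cross is its deviation
from the two parental GCAs. In a co-isogenic background a non-zero SCA can
only arise from dominance-by-dominance epistasis, so significant SCA terms
define enhancer/suppressor edges of an epistatic network.

Estimates use the classical fixed-parent (Model 1) formulas on cross means:

    GCA_i  = T_i/(n-2) - sum(T)/(n(n-2))
    SCA_ij = X_ij - (T_i + T_j)/(n-2) + sum(T)/((n-1)(n-2))

with T_i the sum of cross means involving parent i and sum(T) = sum of all
T_i (twice the sum of the cross means). Standard errors are Griffing's
Model-1 variances with the replicate-level error mean square:

    Var(GCA_i)  = (n-1)/(n(n-2)) * s2
    Var(SCA_ij) = (n-3)/(n-1)   * s2

where s2 is the error variance of one cross mean.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from . import _design
from .data import SEXES


class DiallelData:
    """Replicate vial means of a half-diallel cross.

    Wraps a long table (parent_i, parent_j, sex, vial, value). Validates
    that no selfs are present, each unordered pair appears in a single
    orientation, and there are at least three parents.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"parent_i", "parent_j", "sex", "vial", "value"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"diallel table is missing column(s): {sorted(missing)}")
        frame = frame.copy()
        if (frame["parent_i"] == frame["parent_j"]).any():
            raise ValueError("selfed crosses (i = j) are not part of a half-diallel")
        pairs = set(map(tuple, frame[["parent_i", "parent_j"]].drop_duplicates().to_numpy()))
        for i, j in pairs:
            if (j, i) in pairs:
                raise ValueError(f"cross ({i}, {j}) appears in both orientations")
        self.frame = frame
        self.parents = sorted(set(frame["parent_i"]) | set(frame["parent_j"]))
        if len(self.parents) < 3:
            raise ValueError("a half-diallel needs at least 3 parents")

    @property
    def n_parents(self) -> int:
        return len(self.parents)

    def cross_means(self, sex: str | None = None) -> pd.DataFrame:
        """Symmetric matrix of cross means (NaN diagonal and missing cells).

        ``sex=None`` averages the per-sex cross means (each sex weighted
        equally); otherwise uses that sex's vials only.
        """
        sub = self.frame
        if sex is not None:
            sub = sub[sub["sex"] == sex]
        per_sex = (
            sub.groupby(["parent_i", "parent_j", "sex"])["value"].mean().reset_index()
        )
        cell = per_sex.groupby(["parent_i", "parent_j"])["value"].mean()
        mat = pd.DataFrame(np.nan, index=self.parents, columns=self.parents)
        for (i, j), v in cell.items():
            mat.loc[i, j] = v
            mat.loc[j, i] = v
        return mat

    def check_complete(self) -> None:
        for i, j in itertools.combinations(self.parents, 2):
            sub = self.frame[
                ((self.frame["parent_i"] == i) & (self.frame["parent_j"] == j))
                | ((self.frame["parent_i"] == j) & (self.frame["parent_j"] == i))
            ]
            if len(sub) == 0:
                raise ValueError(f"half-diallel is incomplete: cross ({i}, {j}) is missing")

    def error_ms(self, sex: str | None = None) -> tuple[float, int]:
        """Pooled among-vial error MS within cross x sex, and its df."""
        sub = self.frame if sex is None else self.frame[self.frame["sex"] == sex]
        g = sub.groupby(["parent_i", "parent_j", "sex"])["value"]
        ss = float(((sub["value"] - g.transform("mean")) ** 2).sum())
        df = int(len(sub) - g.ngroups)
        if df < 1:
            raise ValueError("no replicate vials: error variance is inestimable")
        return ss / df, df


@dataclasses.dataclass
class CombiningAbilities:
    """GCA/SCA estimates for one half-diallel (one sex or pooled)."""

    parents: list[str]
    grand_mean: float
    gca: pd.Series
    sca: pd.DataFrame
    se_gca: float
    se_sca: float
    totals: pd.Series          # T_i
    sum_totals: float          # sum(T) = 2 * sum of cross means
    error_ms: float
    error_df: int
    n_means_per_cross: float   # observations behind each cross mean


def combining_abilities(data: DiallelData, sex: str | None = None) -> CombiningAbilities:
    """Estimate GCA and SCA effects from a complete half-diallel.

    ``sex=None`` analyses sex-averaged cross means. The reconstruction
    X_ij = grand_mean + GCA_i + GCA_j + SCA_ij is exact, sum(GCA) = 0 and
    every SCA row sums to zero over the half-diallel.
    """
    data.check_complete()
    n = data.n_parents
    X = data.cross_means(sex=sex)
    T = X.sum(axis=1, skipna=True)  # row totals over the n-1 crosses of each parent
    sum_T = float(T.sum())
    grand_mean = sum_T / (n * (n - 1))
    gca = T / (n - 2) - sum_T / (n * (n - 2))
    sca = X.copy()
    for i, j in itertools.combinations(data.parents, 2):
        val = X.loc[i, j] - (T[i] + T[j]) / (n - 2) + sum_T / ((n - 1) * (n - 2))
        sca.loc[i, j] = val
        sca.loc[j, i] = val
    np.fill_diagonal(sca.values, 0.0)

    ms_e, df_e = data.error_ms(sex=sex)
    sub = data.frame if sex is None else data.frame[data.frame["sex"] == sex]
    counts = sub.groupby(["parent_i", "parent_j"])["value"].count()
    n_per_cross = float(counts.mean())
    s2_mean = ms_e / n_per_cross  # error variance of one cross mean
    se_gca = float(np.sqrt((n - 1) / (n * (n - 2)) * s2_mean))
    se_sca = float(np.sqrt((n - 3) / (n - 1) * s2_mean))
    return CombiningAbilities(
        parents=data.parents,
        grand_mean=grand_mean,
        gca=gca,
        sca=sca,
        se_gca=se_gca,
        se_sca=se_sca,
        totals=T,
        sum_totals=sum_T,
        error_ms=ms_e,
        error_df=df_e,
        n_means_per_cross=n_per_cross,
    )


def _gca_columns(frame: pd.DataFrame, parents: list[str]) -> np.ndarray:
    cols = np.zeros((len(frame), len(parents)))
    idx = {p: k for k, p in enumerate(parents)}
    for r, (i, j) in enumerate(zip(frame["parent_i"], frame["parent_j"])):
        cols[r, idx[i]] = 1.0
        cols[r, idx[j]] = 1.0
    return cols


def diallel_anova(
    data: DiallelData, sex: str | None = None
) -> pd.DataFrame:
    """ANOVA of the half-diallel with the genotype term partitioned into
    GCA and SCA (plus sex-interaction terms when sexes are pooled).

    Pooled model: Y = Sex + GCA + SCA + GCAxSex + SCAxSex + error, with the
    among-replicate-vials-within-cross-and-sex stratum as the error; per-sex
    model: Y = GCA + SCA + error. SS are sequential, and
    SS(GCA) + SS(SCA) equals the among-genotype SS of the unpartitioned
    model for a complete half-diallel.
    """
    data.check_complete()
    sub = data.frame if sex is None else data.frame[data.frame["sex"] == sex]
    if sub.groupby(["parent_i", "parent_j", "sex"])["value"].count().min() < 2:
        raise ValueError("tests need at least two replicate vials per cross per sex")
    y = sub["value"].to_numpy(dtype=float)
    cross = (sub["parent_i"].astype(str) + "×" + sub["parent_j"].astype(str)).to_numpy()
    gca_cols = _gca_columns(sub, data.parents)
    cross_d = _design.dummies(cross)
    blocks = [("Intercept", np.ones((len(y), 1)))]
    if sex is None:
        sx = _design.dummies(sub["sex"])
        contrast = (sub["sex"] == "female").to_numpy(dtype=float) - 0.5
        blocks += [
            ("Sex", sx),
            ("GCA", gca_cols),
            ("SCA", cross_d),
            ("GCA×Sex", gca_cols * contrast[:, None]),
            ("SCA×Sex", cross_d * contrast[:, None]),
        ]
        denom = {k: "Error" for k in ("Sex", "GCA", "SCA", "GCA×Sex", "SCA×Sex")}
    else:
        blocks += [("GCA", gca_cols), ("SCA", cross_d)]
        denom = {"GCA": "Error", "SCA": "Error"}
    seq, _ = _design.sequential_ss(y, blocks)
    table = seq[seq["source"] != "Intercept"].reset_index(drop=True)
    table["ms"] = table["ss"] / table["df"]
    ms = dict(zip(table["source"], table["ms"]))
    dfs = dict(zip(table["source"], table["df"]))
    F, P = [], []
    for _, row in table.iterrows():
        d = denom.get(row["source"])
        if d is None or dfs.get(d, 0) < 1:
            F.append(np.nan)
            P.append(np.nan)
        else:
            f = row["ms"] / ms[d]
            F.append(f)
            P.append(float(stats.f.sf(f, row["df"], dfs[d])))
    table["F"] = F
    table["P"] = P
    return table


def sca_epistasis_calls(
    ca: CombiningAbilities, alpha: float = 0.05
) -> pd.DataFrame:
    """Significant SCA effects as enhancer/suppressor network edges.

    Each SCA is tested with t = SCA/SE against the replicate-error df; a
    significant positive SCA (longer-lived than the GCA expectation) is an
    ``enhancing`` edge, a negative one (pulled back toward wild type) is
    ``suppressing``. Returns all pairs with their call (non-significant
    pairs carry sign ``none``).
    """
    rows = []
    for i, j in itertools.combinations(ca.parents, 2):
        s = float(ca.sca.loc[i, j])
        t = s / ca.se_sca if ca.se_sca > 0 else np.inf * np.sign(s)
        p = float(2 * stats.t.sf(abs(t), ca.error_df))
        sign = "none"
        if p < alpha and s != 0:
            sign = "enhancing" if s > 0 else "suppressing"
        rows.append(
            {
                "parent_i": i,
                "parent_j": j,
                "sca": s,
                "se": ca.se_sca,
                "t": t,
                "p": p,
                "sign": sign,
            }
        )
    return pd.DataFrame(rows)
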
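"""Line-level screening against the co-isogenic control: normal-theory
confidence-interval flags, Dunnett many-to-one tests, standardised
mutational effects, sex-effect classification, and Tukey compact letter
displays for revertant comparisons.
"""

from __future__ import annotations

from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

# Critical values used by the screen: fixed conventional z constants, not
# recomputed quantiles, so the flag boundaries match the original analysis.
Z_ALPHA = {0.95: 1.96, 0.99: 2.575, 0.999: 3.3}

CATEGORIES = (
    "both sexes",
    "male-specific",
    "female-specific",
    "male-biased",
    "female-biased",
    "sex-antagonistic",
    "not significant",
)


def ci_half_width(sigma: float, n_reps: int, level: float) -> float:
    """Half-width z_alpha * sigma / sqrt(n) of the deviation CI."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    if level not in Z_ALPHA:
        raise ValueError(f"level must be one of {sorted(Z_ALPHA)}")
    return Z_ALPHA[level] * sigma / np.sqrt(n_reps)


def _per_sex(value, sex):
    if isinstance(value, Mapping):
        return value[sex]
    return value


def ci_screen(
    deviations: pd.DataFrame,
    sigma: float | Mapping[str, float],
    n_reps: int | Mapping[str, int],
    levels: Sequence[float] = (0.95, 0.99, 0.999),
) -> pd.DataFrame:
    """Flag lines whose deviation from the control exceeds the normal CI.

    A line is flagged at a level iff |deviation| is strictly greater than
    the half-width z_alpha * sigma / sqrt(n) (ties are not significant).
    ``sigma`` is the phenotypic standard deviation of the relevant model —
    sqrt(s2_L + s2_LS + s2_e) for pooled rows, sqrt(s2_L + s2_e) per sex —
    and ``n_reps`` the replicate-vial count of the design; either may be a
    mapping keyed by the ``sex`` column ('male'/'female'/'pooled') or a
    scalar applied to all rows. Flags are nested: significance at 99.9%
    implies 99% implies 95%.
    """
    out = deviations.copy()
    dev = out["deviation"].to_numpy(dtype=float)
    out["direction"] = np.where(dev > 0, "increased", np.where(dev < 0, "decreased", "none"))
    for level in levels:
        half = np.array(
            [
                ci_half_width(_per_sex(sigma, s), _per_sex(n_reps, s), level)
                for s in out["sex"]
            ]
        )
        out[f"sig_{level:g}"] = np.abs(dev) > half
    return out


def _dunnett_mc_pvalues(
    t_obs: np.ndarray,
    ns: np.ndarray,
    n0: int,
    df: int,
    n_draws: int,
    seed: int | None,
) -> np.ndarray:
    """Monte-Carlo adjusted P: P(max_k |T_k| >= |t|) under the joint null.

    Simulates the many-to-one multivariate t directly from its construction
    (shared control mean, independent group means, common pooled scale), so
    unequal replicate counts and their unequal correlations are exact up to
    Monte-Carlo error.
    """
    rng = np.random.default_rng(seed)
    k = len(ns)
    denom = np.sqrt(1.0 / ns + 1.0 / n0)
    exceed = np.zeros(len(t_obs))
    chunk = max(1, int(2_000_000 // max(k, 1)))
    left = n_draws
    while left > 0:
        m = min(chunk, left)
        z0 = rng.standard_normal(m)
        z = rng.standard_normal((m, k))
        w = np.sqrt(rng.chisquare(df, m) / df)
        tmax = np.abs(z / np.sqrt(ns) - z0[:, None] / np.sqrt(n0)) / denom
        tmax = (tmax.max(axis=1)) / w
        exceed += (tmax[:, None] >= np.abs(t_obs)[None, :]).sum(axis=0)
        left -= m
    return exceed / n_draws


def dunnett_test(
    vials: pd.DataFrame,
    control_line: str,
    value_col: str = "mean_lifespan",
    by: Sequence[str] = ("block", "sex"),
    method: str = "auto",
    n_mc: int = 200_000,
    mc_seed: int | None = 0,
) -> pd.DataFrame:
    """Dunnett many-to-one comparisons of every line against the control.

    Runs within each group of ``by`` (by default per block and sex, so the
    familywise error is controlled over the lines of one contemporaneous
    block). Two-sided adjusted P values come from the equicorrelated
    multivariate-t distribution (``method='mvt'``) or a Monte-Carlo max-|t|
    simulation (``method='mc'``; draw count and seed configurable).
    ``'auto'`` uses the multivariate-t quadrature for families of up to 20
    comparisons and Monte Carlo beyond, where the quadrature becomes
    impractically slow. Unequal replicate counts are handled by both paths.
    """
    if method not in ("auto", "mvt", "mc"):
        raise ValueError("method must be 'auto', 'mvt' or 'mc'")
    cols = [c for c in by if c in vials.columns]
    results = []
    for keys, sub in vials.groupby(list(cols)) if cols else [((), vials)]:
        if not isinstance(keys, tuple):
            keys = (keys,)
        ctrl = sub.loc[sub["line"] == control_line, value_col].to_numpy(dtype=float)
        if len(ctrl) == 0:
            raise ValueError(
                f"control line {control_line!r} absent in group {dict(zip(cols, keys))}"
            )
        lines = [l for l in sub["line"].unique() if l != control_line]
        if not lines:
            continue
        samples = [
            sub.loc[sub["line"] == l, value_col].to_numpy(dtype=float) for l in lines
        ]
        use = method if method != "auto" else ("mvt" if len(lines) <= 20 else "mc")
        if use == "mvt":
            res = stats.dunnett(*samples, control=ctrl)
            t_obs, pvals = res.statistic, res.pvalue
        else:
            ns = np.array([len(s) for s in samples], dtype=float)
            n0 = len(ctrl)
            df = int(len(sub) - len(lines) - 1)
            group_means = np.array([s.mean() for s in samples])
            ctrl_mean = ctrl.mean()
            sse = sum(((s - s.mean()) ** 2).sum() for s in samples)
            sse += ((ctrl - ctrl_mean) ** 2).sum()
            s_pooled = np.sqrt(sse / df)
            t_obs = (group_means - ctrl_mean) / (s_pooled * np.sqrt(1 / ns + 1 / n0))
            pvals = _dunnett_mc_pvalues(t_obs, ns, n0, df, n_mc, mc_seed)
        for line, t, p in zip(lines, t_obs, pvals):
            row = dict(zip(cols, keys))
            row.update({"line": line, "statistic": float(t), "p_adjusted": float(p)})
            results.append(row)
    return pd.DataFrame(results)


class MutationalEffect(NamedTuple):
    percent: float
    a: float
    a_over_sigma_p: float


def mutational_effect(
    mutant_mean: float, control_mean: float, control_sigma_p: float
) -> MutationalEffect:
    """Percent deviation, allelic effect a, and standardised effect a/sigma_P.

    ``a`` is one half the homozygote difference (mutant mean minus control
    mean over two) and sigma_P the phenotypic standard deviation of the
    control line, so a/sigma_P expresses the mutation in control phenotypic
    standard deviations.
    """
    if control_mean <= 0:
        raise ValueError("control mean must be positive")
    if control_sigma_p <= 0:
        raise ValueError("control phenotypic standard deviation must be positive")
    diff = mutant_mean - control_mean
    return MutationalEffect(
        percent=100.0 * diff / control_mean,
        a=diff / 2.0,
        a_over_sigma_p=diff / 2.0 / control_sigma_p,
    )


def classify_sex_effect(
    p_line: float,
    p_line_sex: float,
    p_line_male: float,
    p_line_female: float,
    alpha: float = 0.05,
    effect_male: float | None = None,
    effect_female: float | None = None,
    marginal_alpha: float = 0.1,
) -> str:
    """Classify a mutation's sex pattern from its ANOVA significance pattern.

    ``p_line``/``p_line_sex`` are the Line and Line-by-Sex P values of the
    sexes-pooled mutant-versus-control ANOVA; ``p_line_male``/``p_line_female``
    the Line P values of the separate-sex analyses.

    Rules: significant Line with a non-significant interaction affects both
    sexes. A significant interaction with only one sex significant is
    sex-specific; with both sexes significant it is sex-biased when the
    effects agree in direction (labelled by the more significant sex) and
    sex-antagonistic when they oppose (or, absent direction information,
    when the pooled Line term is not significant — opposing effects cancel
    in the pooled analysis).

    When per-sex deviations are supplied two refinements apply: opposite
    signs override the biased call, and a sex that is only marginal
    (alpha < P < ``marginal_alpha``) but opposite in sign to a significant
    sex still yields an antagonistic call.
    """
    for p in (p_line, p_line_sex, p_line_male, p_line_female):
        if not (0 <= p <= 1):
            raise ValueError("P values must lie in [0, 1]")
    sig = lambda p: p < alpha
    have_signs = effect_male is not None and effect_female is not None
    opposite = have_signs and (np.sign(effect_male) * np.sign(effect_female) < 0)

    if sig(p_line_sex):
        m, f = sig(p_line_male), sig(p_line_female)
        if m and f:
            if opposite:
                return "sex-antagonistic"
            if not sig(p_line) and not have_signs:
                return "sex-antagonistic"
            if not sig(p_line) and have_signs and not opposite:
                # same-direction effects that cancel enough to mute the pooled
                # Line term are still treated as antagonistic sexual conflict
                return "sex-antagonistic"
            if p_line_male < p_line_female:
                return "male-biased"
            if p_line_female < p_line_male:
                return "female-biased"
            if have_signs:
                return "male-biased" if abs(effect_male) >= abs(effect_female) else "female-biased"
            return "male-biased"
        if m != f:
            which = "male" if m else "female"
            other_p = p_line_female if m else p_line_male
            if have_signs and opposite and alpha <= other_p < marginal_alpha:
                return "sex-antagonistic"
            return f"{which}-specific"
        return "both sexes" if sig(p_line) else "not significant"

    if sig(p_line):
        return "both sexes"
    m, f = sig(p_line_male), sig(p_line_female)
    if m and f:
        return "both sexes"
    if m != f:
        return "male-specific" if m else "female-specific"
    return "not significant"


def tukey_letters(
    group_means: Mapping[str, float],
    error_ms: float,
    error_df: int,
    n_per_group: int | Mapping[str, int],
    alpha: float = 0.05,
) -> dict[str, str]:
    """Compact letter display from all-pairs studentized-range (Tukey) tests.

    Groups sharing a letter are not significantly different at ``alpha``.
    Unequal group sizes use the Tukey-Kramer standard error. Letters are
    assigned by the insert-and-absorb construction, ordered by group mean.
    """
    names = sorted(group_means, key=lambda g: group_means[g])
    k = len(names)
    if k < 2:
        raise ValueError("need at least two groups")
    if error_ms < 0:
        raise ValueError("error mean square must be non-negative")

    def n_of(g):
        return n_per_group[g] if isinstance(n_per_group, Mapping) else n_per_group

    sig = {}
    for a_i in range(k):
        for b_i in range(a_i + 1, k):
            ga, gb = names[a_i], names[b_i]
            diff = abs(group_means[ga] - group_means[gb])
            se = np.sqrt(error_ms / 2 * (1 / n_of(ga) + 1 / n_of(gb)))
            if se == 0:
                if diff > 0:
                    raise ValueError(
                        "zero error mean square with unequal means: tests are degenerate"
                    )
                sig[(ga, gb)] = False
                continue
            q = diff / se
            sig[(ga, gb)] = float(stats.studentized_range.sf(q, k, error_df)) < alpha

    # insert-and-absorb: split any letter set containing a significant pair
    letters: list[set[str]] = [set(names)]
    for (ga, gb), s in sorted(sig.items()):
        if not s:
            continue
        new = []
        for group_set in letters:
            if ga in group_set and gb in group_set:
                new.append(group_set - {ga})
                new.append(group_set - {gb})
            else:
                new.append(group_set)
        letters = [s1 for s1 in new if not any(s1 < s2 for s2 in new)]
        # deduplicate
        seen, uniq = set(), []
        for s1 in letters:
            key = frozenset(s1)
            if key not in seen:
                seen.add(key)
                uniq.append(s1)
        letters = uniq
    letters.sort(key=lambda s: min(names.index(g) for g in s))
    out = {g: "" for g in names}
    for idx, group_set in enumerate(letters):
        ch = chr(ord("a") + idx)
        for g in group_set:
            out[g] += ch
    return out
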
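#!/usr/bin/env python
"""Line-level screen: CI flags, Dunnett tests, standardised effects, and
sex-effect classification against the co-isogenic control.

Flags each line whose deviation from the contemporaneous control exceeds
the 95/99/99.9% normal confidence interval (z = 1.96/2.575/3.3, sigma from
the estimated components, n = 4 pooled and 2 per sex), runs Dunnett
many-to-one tests per sex, computes percent deviations and a/sigma_P, and
classifies each flagged line's sex pattern from mutant-versus-control
ANOVAs (pooled, with replicate vials nested in line-by-sex, and per sex).
"""

from pathlib import Path

import numpy as np
import pandas as pd

import lifescreen as ls

RESULTS = Path(__file__).resolve().parents[1] / "results"


def classify_line(records: pd.DataFrame, line: str, control: str) -> str:
    sub = records[records["line"].isin([line, control])]
    pooled = ls.nested_individual_anova(sub).set_index("source")
    # per-sex reduced model on the one-way vial-mean layout
    p_sex = {}
    for sex in ls.SEXES:
        ssub = sub[sub["sex"] == sex]
        vm = ls.vial_means(ssub)
        table, _ = ls.per_sex_anova(vm, sex)
        p_sex[sex] = table.set_index("source").loc["Line", "P"]
    means = sub.groupby(["line", "sex"])["death_age"].mean()
    eff = {s: means[(line, s)] - means[(control, s)] for s in ls.SEXES}
    return ls.classify_sex_effect(
        pooled.loc["Line", "P"], pooled.loc["Line×Sex", "P"],
        p_sex["male"], p_sex["female"],
        effect_male=eff["male"], effect_female=eff["female"],
    )


def main() -> None:
    path = RESULTS / "screen_survival.csv"
    comp_path = RESULTS / "screen_components.csv"
    if not path.exists() or not comp_path.exists():
        raise SystemExit("run analysis/01 and analysis/02 first")
    records = ls.read_survival_table(path)
    comp = pd.read_csv(comp_path).iloc[0]

    vials = ls.vial_means(records)
    dev = ls.deviations_from_control(vials, "control")
    dev = dev[dev["line"] != "control"]

    sigma = {
        "pooled": float(np.sqrt(comp["sigma2_line"] + comp["sigma2_line_sex"]
                                + comp["sigma2_error"])),
        "male": float(np.sqrt(comp["sigma2_line_male"] + comp["sigma2_error"])),
        "female": float(np.sqrt(comp["sigma2_line_female"] + comp["sigma2_error"])),
    }
    flags = ls.ci_screen(dev, sigma=sigma, n_reps={"pooled": 4, "male": 2, "female": 2})
    dunnett = ls.dunnett_test(vials, "control")

    ctrl = records[records["line"] == "control"]
    ctrl_mean = ctrl.groupby("sex")["death_age"].mean()
    ctrl_sigma = ctrl.groupby(["sex", "vial"])["death_age"].mean().groupby("sex").std()
    effects = []
    for line, sub in records[records["line"] != "control"].groupby("line"):
        for sex in ls.SEXES:
            eff = ls.mutational_effect(
                sub.loc[sub["sex"] == sex, "death_age"].mean(),
                ctrl_mean[sex], ctrl_sigma[sex],
            )
            effects.append({"line": line, "sex": sex, "percent": eff.percent,
                            "a": eff.a, "a_over_sigma_p": eff.a_over_sigma_p})
    effects = pd.DataFrame(effects)

    pooled_flags = flags[flags["sex"] == "pooled"]
    n = pooled_flags["line"].nunique()
    n95 = int(pooled_flags["sig_0.95"].sum())
    inc = int((pooled_flags["sig_0.95"] & (pooled_flags["direction"] == "increased")).sum())
    dec = n95 - inc
    print(f"{n} lines screened; {n95} flagged at the 95% CI pooled across "
          f"sexes ({inc} increased, {dec} decreased)")
    n_dunnett = dunnett.loc[dunnett["p_adjusted"] < 0.05, "line"].nunique()
    print(f"Dunnett tests flag {n_dunnett} lines (either sex, familywise 5%)")

    flagged_inc = sorted(pooled_flags.loc[
        pooled_flags["sig_0.95"] & (pooled_flags["direction"] == "increased"), "line"
    ])
    cats = {line: classify_line(records, line, "control") for line in flagged_inc}
    cat_table = pd.Series(cats, name="category").rename_axis("line").reset_index()
    counts = cat_table["category"].value_counts()
    print(f"\nsex-effect categories of the {len(flagged_inc)} increased lines:")
    for cat, k in counts.items():
        print(f"  {cat}: {k}")

    flags.to_csv(RESULTS / "screen_ci_flags.csv", index=False)
    dunnett.to_csv(RESULTS / "screen_dunnett.csv", index=False)
    effects.to_csv(RESULTS / "screen_effects.csv", index=False)
    cat_table.to_csv(RESULTS / "screen_categories.csv", index=False)
    print(f"\nwrote screen_ci_flags.csv, screen_dunnett.csv, "
          f"screen_effects.csv, screen_categories.csv in {RESULTS}")


if __name__ == "__main__":
    main()
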
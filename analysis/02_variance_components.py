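#!/usr/bin/env python
"""Variance components, mutational heritability, and the cross-sex genetic
correlation of the simulated screen.

Runs the sexes-pooled two-factor mixed ANOVA and the per-sex one-way
ANOVAs on vial means, estimates variance components by method of moments,
and reports H^2 = (s2_L + s2_LS)/(s2_L + s2_LS + s2_e) and
r_MF = cov_FM/(s_LM s_LF) by both numerator conventions (pooled line
component, and the covariance of per-line sex means).
"""

from pathlib import Path

import pandas as pd

import lifescreen as ls

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    path = RESULTS / "screen_survival.csv"
    if not path.exists():
        raise SystemExit("run analysis/01_simulate_screen.py first")
    records = ls.read_survival_table(path)
    vials = ls.vial_means(records[records["line"] != "control"])

    pooled_table, vc = ls.two_factor_mixed_anova(vials)
    male_table, vc_m = ls.per_sex_anova(vials, "male")
    female_table, vc_f = ls.per_sex_anova(vials, "female")
    vc.sigma2_line_male = vc_m.sigma2_line_male
    vc.sigma2_line_female = vc_f.sigma2_line_female

    tables = pd.concat(
        [pooled_table.assign(analysis="sexes pooled"),
         male_table.assign(analysis="males"),
         female_table.assign(analysis="females")]
    )
    tables.to_csv(RESULTS / "screen_anova.csv", index=False)

    h2 = ls.heritability(vc)
    r_pooled = ls.cross_sex_genetic_correlation(vc)
    vc.cov_fm = ls.line_sex_mean_covariance(vials)
    r_cov = ls.cross_sex_genetic_correlation(vc)

    print("sexes-pooled ANOVA of vial means:")
    print(pooled_table.to_string(index=False))
    print(f"\nvariance components (days^2): line {vc.sigma2_line:.2f}, "
          f"line-by-sex {vc.sigma2_line_sex:.2f}, error {vc.sigma2_error:.2f}")
    print(f"per-sex line components: male {vc.sigma2_line_male:.2f}, "
          f"female {vc.sigma2_line_female:.2f}")
    print(f"\nmutational heritability H^2 = {h2:.3f}")
    print(f"cross-sex genetic correlation r_MF = {r_pooled.value:.3f} "
          f"(pooled-component numerator)")
    print(f"cross-sex genetic correlation r_MF = {r_cov.value:.3f} "
          f"(line-mean covariance numerator)")

    summary = pd.DataFrame(
        [{"sigma2_line": vc.sigma2_line, "sigma2_line_sex": vc.sigma2_line_sex,
          "sigma2_error": vc.sigma2_error,
          "sigma2_line_male": vc.sigma2_line_male,
          "sigma2_line_female": vc.sigma2_line_female,
          "H2": h2, "r_MF_pooled": r_pooled.value, "r_MF_cov": r_cov.value}]
    )
    summary.to_csv(RESULTS / "screen_components.csv", index=False)
    print(f"\nwrote {RESULTS / 'screen_anova.csv'} and screen_components.csv")


if __name__ == "__main__":
    main()
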
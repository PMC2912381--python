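# Methods

`lifescreen` implements the statistical pipeline of a large-scale screen
for induced mutations affecting *Drosophila* life span: hundreds to
thousands of co-isogenic single-P-element insertion lines are assayed in
replicate vials of same-sex flies alongside their unmutagenised control
strain, and the questions are (i) how much mutational variance the
insertions contribute and how heritable it is, (ii) which individual lines
deviate from the control and in which sex, (iii) whether long-lived
mutations interact epistatically, and (iv) what pleiotropic costs they
carry. This note records the models, conventions, and numerical choices.

## Data model

The atomic observation is one fly's death age. Deaths are scored on a
census grid (default every 2 days, first census at day 2): the recorded
age is the census day on or after true death, with no midpoint correction
— the grid day *is* the life span value. Flies are raised in replicate
vials nested within line × sex × block; all lifespan analyses of the
primary screen operate on vial means. Deviations from the control are
always computed within experimental block ("contemporaneous"), per sex,
with the pooled deviation the unweighted mean of the two sex deviations.
There is no censoring: the protocol runs until all flies are dead, so no
survival-curve or Kaplan–Meier machinery is used or needed.

## ANOVA models and variance components

Three layouts (L = line, S = sex, R = replicate vial, ε = residual):

* sexes pooled, vial means: `Y = μ + L + S + L×S + ε`, L random, S fixed;
* one sex, vial means: `Y = μ + L + ε`;
* individuals, mutant vs control: `Y = μ + L + S + L×S + R(L×S) + ε`,
  with L fixed and the replicate-vial stratum separated from within-vial
  error. L, S and L×S are tested over the replicate stratum, R over ε.

Sums of squares are sequential (S before L before L×S), which coincides
with the orthogonal decomposition whenever the design is balanced.
Variance components come from equating observed to expected mean squares.
Balanced designs use the textbook closed forms (for r vials per cell and
two sexes: E[MS_L] = σ²ε + rσ²LS + 2rσ²L, E[MS_LS] = σ²ε + rσ²LS under
the unrestricted mixed-model convention, which is the default and the only
convention consistent with treating the L×S mean square this way).
Unbalanced designs derive the expectation coefficients from the actual
incidence matrices as traces of projection differences (generalised
Henderson Method III); the two paths agree exactly on balanced data, which
the tests assert. Negative component estimates are truncated to zero
after estimation, before any ratio is formed, and the truncation is
flagged in the output.

F statistics use the error mean square as denominator for every term by
default. A conservative mixed-model test of L would use the L×S mean
square instead; the error-MS convention is the one the screen's published
F ratios follow, and the denominator map is a configurable argument.

Derived quantities:

* mutational heritability `H² = (σ²L + σ²LS)/(σ²L + σ²LS + σ²ε)`;
* cross-sex genetic correlation `r_MF = cov_FM/(σ_LM σ_LF)`. Because male
  and female flies occupy different vials, the covariance of per-line sex
  means estimates cov_FM directly; the published component tables instead
  use the pooled-model σ²L as numerator. Both numerators are provided
  (`cov_fm` when set, pooled σ²L otherwise); on balanced data they give
  identical estimates. Ratios outside [−1, 1] are clamped with a flag.

## Line-level screening

**CI screen.** A line is flagged at level α when its absolute deviation
from the control strictly exceeds `z_α σ/√n` with the fixed conventional
constants z = 1.96, 2.575, 3.3 (95/99/99.9%), σ the phenotypic standard
deviation of the relevant model (`√(σ²L+σ²LS+σ²ε)` pooled,
`√(σ²L+σ²ε)` per sex) and n the replicate-vial count (4 pooled, 2 per sex
in the primary design). Ties at the boundary are not significant (the
convention is a package choice; the source analysis is silent). Flags are
nested across levels by construction.

**Dunnett.** Many-to-one comparisons against the control are run within
block and sex. Families of up to 20 comparisons use the multivariate-t
quadrature (`scipy.stats.dunnett`); larger families — screens run blocks
of 50–100 lines — switch to a seeded, vectorised Monte-Carlo max-|t|
simulation built from the same joint-null construction (shared control
mean, pooled scale), with the draw count configurable (default 200,000,
Monte-Carlo SE ≈ 0.0005 at P ≈ 0.05). The two paths agree to ~0.01 on
small families. Tests are two-sided.

**Effect sizes.** `a` is one half the mutant-minus-control mean
difference (the homozygous allelic effect), and `a/σ_P` standardises it by
the control line's phenotypic standard deviation. Percent deviation is
100 × (mutant − control)/control.

**Sex-effect classification.** From the mutant-versus-control ANOVAs, a
line is classified as affecting *both sexes* (L significant, L×S not),
*sex-specific* (L×S significant, per-sex L significant in one sex only),
*sex-biased* (L and L×S significant, both sexes significant, effects in
the same direction; labelled by the more significant sex), or
*sex-antagonistic* (both sexes significant with opposite-signed effects,
or a non-significant pooled L — opposing effects cancel in the pooled
analysis). α = 0.05. When per-sex effect directions are supplied, two
refinements apply that the P-value pattern alone cannot express: opposite
signs override a biased call, and a sex that is only marginal
(0.05 < P < 0.1) but opposite in sign to a significant sex still yields an
antagonistic call. Published category assignments in comparable screens
require exactly these refinements, so signless classification is
supported but documented as the coarser rule.

**Revertant comparisons.** Control/mutant/revertant contrasts use
all-pairs Tukey (studentized-range) tests with a compact letter display
built by insert-and-absorb: two groups share a letter if and only if their
pairwise test is not significant at α = 0.05; Tukey–Kramer standard errors
cover unequal group sizes.

## Half-diallel combining abilities

All n(n−1)/2 pairwise crosses among n homozygous parent lines (no selfs,
no reciprocals) are analysed with parents fixed (Griffing Method 4,
Model 1). On cross means X_ij:

    GCA_i  = T_i/(n−2) − ΣT/(n(n−2))
    SCA_ij = X_ij − (T_i + T_j)/(n−2) + ΣT/((n−1)(n−2))

with T_i the sum of cross means involving parent i. These closed forms
are the constrained least-squares solution (ΣGCA = 0, SCA rows sum to
zero), reconstruct every cross mean exactly, and are asserted against an
independent normal-equations oracle in the tests. Standard errors are the
classical Griffing Model-1 variances, Var(GCA_i) = (n−1)/(n(n−2))·s²,
Var(SCA_ij) = (n−3)/(n−1)·s², with s² the replicate-error variance of one
cross mean; the original analysis used a SAS macro whose exact SE
constructions are not published, so the classical formulas are the
documented reference. The diallel ANOVA partitions the among-genotype SS
into GCA (df n−1) and SCA (df n(n−3)/2), plus GCA×S and SCA×S when sexes
are pooled, all tested against the replicate-vial stratum; the partition
is a projection decomposition, so SS(G) = SS(GCA) + SS(SCA) exactly.
Incomplete diallels are rejected rather than imputed — the closed forms
assume completeness. Significant SCA terms become network edges: positive
SCA (longer-lived than the GCA expectation) = enhancing epistasis,
negative = suppressing.

Only the doubly-centred projection of an SCA parameter matrix is
estimable. A matrix with exactly k isolated non-zero cells cannot satisfy
the zero-row-sum constraint, so planting k spikes leaks roughly
2/(n−2) of each spike into the other cells of the same rows; planted-
signal experiments therefore size spikes on the projected scale and test
detection of the planted edges, not exact support recovery, which has
vanishing probability even at 5-SE spikes.

## Pleiotropy correlations

Pairwise Pearson correlations of line-mean deviations, per trait pair ×
sex × age, with pairwise-complete line matching (a trait scored on only a
subset of lines shrinks only its own pairs; df = complete lines − 2).
`SE = √((1−r²)/df)` and `t = r/SE` against zero. The test against unity
uses the one-sided t statistic `(1−r)/SE(r)` with the same SE: it matches
the r ± SE reporting convention, P is monotone non-decreasing in r, and
P → 0.5 as r → 1⁻ (no exact test exists at the boundary; a Fisher-z
comparison against a fixed boundary was considered and rejected because
the boundary choice is arbitrary). Cells with fewer than three complete
pairs are marked inestimable. Chill coma recovery is analysed as raw
recovery time; any "shorter is fitter" sign flip is presentation only.

## Synthetic-data generators

All randomness flows from one integer seed through a
`numpy.random.SeedSequence` splitting scheme with one child stream per
model stratum (line effects / interactions / vial / individual), so a
dataset is byte-reproducible and per-stratum draws are stable.

* **Screen**: lifespan = μ + sex effect + line + line×sex + vial +
  individual draws (all normal), snapped up to the census grid and
  truncated below at the first census day. Defaults are the study
  conditions: 1,332 lines, 2 vials × 5 flies per sex per line, 10 control
  vials per sex, 2-day census, line and line×sex components 31.39 and
  25.24 days², and a vial-mean error of 45.02 days² decomposed as
  σ²vial = 25 plus σ²individual = 100 over 5 flies (the split is
  unidentifiable from vial-mean tables; this decomposition is the
  package's fixed choice). μ = 55 d and a 2-day sex effect match control
  means of comparable assays. Grid snapping adds ≈ interval²/12 ≈ 0.33
  days² to the individual variance and a +1 day location shift; both are
  negligible at these magnitudes and are absorbed into the recovery
  tolerances.
* **Diallel**: E[X_ij] = μ + g_i + g_j + s_ij with ±sex-interaction terms,
  replicate vial values add N(0, σ²vial + σ²error) noise. Defaults: 10
  parents (45 crosses), 8 vials per cross per sex.
* **Pleiotropy**: multivariate-normal line-mean deviations over
  trait × sex × age cells with a user covariance (PSD required, checked by
  eigenvalue; rank-deficient accepted). The default covariance is
  separable — a cross-trait correlation matrix (life-span/stress ≈ +0.3,
  starvation/climbing ≈ −0.33) Kronecker same-trait cross-sex 0.7 and
  cross-age 0.5 — with unit variances, emulating standardised deviations
  of 50 lines with climbing scored on 40.

What the generators do **not** emulate: right-skewed or Gompertz-shaped
mortality (analyses are on means, so only second moments matter), block
heterogeneity beyond a single block label, non-normal line-effect
distributions, and frailty-driven vial-mean variance heterogeneity.
Passing parameter-recovery tests therefore certifies the estimators under
the stated normal components model, not robustness to those departures.

## Problem sizes and tolerances in the test-suite

Simulation-based checks run at reduced but adequately powered sizes, a
package choice balancing resolution against runtime: parameter recovery
uses 20 replicate screens of 500 lines (components within 15% relative
error and H² within 0.05 on the replicate mean); null calibrations use
500 simulations each for the Dunnett familywise rate and the diallel SCA
test, and a single 1,000-line screen for the CI false-positive rate, with
binomial tolerance bands (0.03–0.075 around 0.05). Algebraic identities
are asserted at 1e−10 (reconstruction, GCA/SCA constraints) and 1e−8
(least-squares oracle equivalence, SS additivity). Monte-Carlo Dunnett
agreement with the quadrature is asserted at 0.01 absolute on adjusted P.

## Known limitations

* Method-of-moments components are reported; REML is not implemented
  (the method-of-moments estimates are the reference the published tables
  use, and the error-denominator F convention does not depend on it).
* The CI screen treats σ as known; with σ estimated from the same data
  the false-positive rate is only asymptotically nominal.
* The sex-effect classifier is a deterministic rule on P values and
  effect signs; it inherits the multiple-testing behaviour of its input
  ANOVAs and applies no correction of its own (the Bonferroni threshold
  for the secondary screen is a separate, configurable α).
* Dunnett Monte-Carlo P values carry simulation error (~5e−4 at the
  default draw count); quadrature is used whenever the family is small
  enough to afford it.
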
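# Methods

This note documents the statistical model behind `mrphewas`, the choices made
where the design was genuinely open, and what the synthetic-data generator
does and does not emulate.

## The design being modelled

The package implements a phenome-wide Mendelian randomization (MR-pheWAS)
design: a weighted genetic risk score (GRS) for age at menarche is used as a
single instrumental variable and tested against a large phenome of
health-related traits, followed by a suite of one- and two-sample MR
estimators for traits selected for follow-up. The causal diagram assumed
throughout is:

- independent variants Z affect the exposure X (age at menarche, years);
- a designated subset of variants also affects childhood BMI directly
  (**horizontal pleiotropy** — a bias path);
- adult BMI lies downstream of both childhood BMI and the exposure
  (**vertical pleiotropy** — part of the effect being estimated);
- phenome traits Y may depend on X directly and/or through adult BMI.

## Synthetic cohorts

Genotypes are Hardy–Weinberg, linkage-equilibrium dosages
`Binomial(2, eaf)`. The instrument panel draws effect-allele frequencies
uniformly (default [0.05, 0.95]) and scales per-allele effects so the
analytic variance explained, `sum_j 2 p_j (1 - p_j) beta_j^2`, equals a
configured fraction (default 6.1%) of the exposure variance. Exposure
defaults are mean 12.9 y and SD 1.6 y; the residual SD is solved so the
marginal SD hits the target. Genetic contributions enter centred at their
expectation `2*eaf`, so the configured mean is the marginal mean.

Defaults for the mediator paths (adult BMI on an SD-like scale): childhood →
adult BMI tracking 0.5, exposure → adult BMI −0.1 SD per year, residual SD
0.8. These are chosen as plausible magnitudes for the BMI/menarche
literature; they are configuration, not estimates.

Traits are built from a latent Gaussian:
`latent = beta * ((1 - w) * (X - mean) + w * adult_BMI) + pleiotropy + noise`
with mediation weight `w in [0, 1]`. Binary and ordered traits threshold the
latent at cut-points solved from the requested prevalence / level count
(empirical quantiles); unordered traits are drawn from a softmax over
per-level loadings on the centred latent, so a null latent carries no score
signal. One master seed expands into per-stage `SeedSequence` substreams;
adding a trait never perturbs the genotype draws, and the whole generator is
a pure function of (panel, params, seed).

What the generator does **not** emulate: linkage disequilibrium, imputation
uncertainty, X-chromosome dosage, relatedness, missing-not-at-random
phenotypes, or UK-Biobank-style field codings. Passing tests therefore show
that the procedures are correct under the assumed causal structure — not
that real-biobank complications are handled.

## Instruments

The GRS counts menarche-*decreasing* alleles: a variant with a positive
per-allele effect is re-oriented (dosage `2 - d`, weight `|beta|`), so a
higher score means genetically earlier menarche. Instrument strength is
reported as the incremental R² of the score over a covariate-only linear
model and the partial F of the score term, `F = (RSS0 - RSS1)/(RSS1/dof)`.

Exclusion strategies:

- **Steiger filtering**: a variant is excluded iff its squared sample
  correlation with the competing trait (default adult BMI) strictly exceeds
  that with the exposure. Ties keep the variant. Computed from
  individual-level data.
- **Proximity filtering**: excluded iff on the same chromosome within
  `window_bp` (default 500,000, boundary **inclusive**) of any listed
  reference hit, or if the rsid matches a hit. Applied against any listed
  hit, not lead SNPs only; both choices are configurable.

## Phenome scan

Trait typing: a declared kind wins; otherwise two distinct values → binary;
integer-coded with ≤ 20 distinct values → ordered; non-numeric → unordered;
else continuous. The distinct-value cutoff (20) and binary minority-case
floor (50) are configurable; both are pragmatic defaults for automated
rule-based scans. Continuous traits are inverse-normal rank transformed with
the Blom offset 3/8 (configurable), ties averaged.

Dispatch: linear (OLS), logistic, ordered logistic, or multinomial logistic
regression of the trait on the score plus covariates (default: age and 10
genetic principal components). Multinomial traits report only a
likelihood-ratio p with `levels - 1` degrees of freedom against the
covariate-only model, with the most frequent category as reference.
Two-sided p-values for the other branches use the large-sample normal,
appropriate for the biobank-scale n the scan targets.

Multiple testing: the rank-based FDR rule `P_t(rank) = q * rank / n`, where
rank is the **largest** rank with `p_(rank) < P_t` — the inequality is
strict, so ties at the threshold are non-discoveries (this can diverge from
step-up Benjamini–Hochberg, which uses ≤). Bonferroni is `alpha / n`.
QQ data flags p-values below the double-precision floor 2.23e-308.

## MR estimators

All two-sample methods consume harmonized per-variant pairs
(`beta_exp, se_exp, beta_out, se_out`). Harmonization aligns outcome rows to
the exposure's effect allele, resolves strand by complementing, and drops
palindromic variants whose exposure EAF is within 0.08 of 0.5.

- **Wald ratio**: `beta_out / beta_exp`; first-order delta SE
  `|se_out / beta_exp|` (exposure uncertainty ignored — standard for strong
  instruments; a second-order option exists).
- **IVW**: fixed effects with weights `1/se^2`; random effects add a
  DerSimonian–Laird tau². Cochran's Q and `I² = max(0, (Q - df)/Q)` reported.
- **MR-Egger**: weighted least squares of outcome on exposure effects with
  an intercept, rows oriented so `beta_exp >= 0`, weights `1/se_out^2`;
  multiplicative overdispersion scale floored at 1; p from t with
  `n_snps - 2` df. The intercept estimates directional pleiotropy under
  InSIDE.
- **Weighted median**: ratios ordered, cumulative normalized
  inverse-variance weights interpolated at 0.5. If a single variant carries
  a strict weight majority its own ratio is returned exactly (plain
  interpolation would not honour that dominance property). SE by parametric
  bootstrap (SD of replicates).
- **Mode-based**: normal-kernel density over the ratios, bandwidth
  `phi * 0.9 * min(SD, normalized MAD) * m^(-1/5)` (phi = 1 default), argmax
  on a 10,000-point grid spanning the ratios ± 3 bandwidths; the weighted
  variant scales kernels by normalized inverse-variance weights. The
  bootstrap SE uses the normalized MAD of the replicates: the bootstrap
  distribution of a mode can scatter across secondary humps, and the plain
  SD is then badly conservative.
- **MR-PRESSO**: observed statistic is the weighted residual sum of squares
  of each variant's outcome effect around its leave-one-out IVW prediction.
  The null is simulated parametrically (both exposure and outcome effects
  redrawn) **with leave-one-out predictions recomputed on each simulated
  dataset** — without that recomputation the global test is anticonservative
  because the observed statistic absorbs leave-one-out estimation noise that
  fixed-prediction resampling lacks. Per-variant outlier p-values are
  Bonferroni-corrected; note this bounds resolvable p at
  `m/(n_sim + 1)`, so at least ~20·m simulations are needed (the package
  warns otherwise; default 1000). The outlier-adjusted IVW estimate is
  flagged for reporting only when both the global and distortion p are
  below 0.05.
- **One-sample 2SLS**: stage 1 regresses exposure on score (+ covariates);
  stage 2 regresses the outcome (logistic if binary) on the predicted
  exposure. SEs from a nonparametric bootstrap over individuals re-running
  *both* stages. Stage-1 partial F below 10 sets a weak-instrument flag.
- **Multivariable MR**: every exposure regressed on all scores jointly,
  outcome on all predicted exposures; per-exposure direct effects with
  bootstrap SEs; near-perfectly correlated scores are rejected naming the
  pair.

Estimates are computed on the natural per-year-*increase* scale;
`per_year_decrease()` flips sign and interval at the reporting layer, which
is the orientation the pipeline writes.

## Power

Standard 2SLS asymptotics with noncentrality `sqrt(n * R2_xz) * beta`:
`MDE = (z_{1-alpha/2} + z_{power}) / sqrt(n * R2_xz)` in SD-per-SD units;
binary designs divide the effective information by the case-fraction
variance `p(1-p)` and report the MDE on the log-odds scale (and as an odds
ratio). `power_at_effect` is the exact inverse.

## Numerical choices and degenerate inputs

- Zero-variance score: instrument strength returns R² = 0 with a warning.
- Constant trait columns: flagged and skipped ("no variation"), never
  silently dropped; per-variant GWAS rows likewise carry an `error` field.
- Identical Wald ratios: mode returns the common ratio with SE 0; zero
  spread with nonzero range falls back to a range-based bandwidth.
- Random-effects IVW with one variant falls back to fixed with a warning.
- p-values are clipped to [2.23e-308, 1].

## Monte-Carlo sizes in the test suite

Validation simulations run at the design's stated scale where that matters
(n = 20,000 per scan-calibration replicate; two-sample summary statistics at
n = 50,000/50,000; 50-SNP panels) and use replicate counts chosen for a
desk-scale suite: 200 replicates for calibration/coverage checks (acceptance
bands use exact binomial intervals at the replicate count actually run),
100 for the bootstrap-heavy one-sample/multivariable checks, 50 for
outlier-detection rates, and a 1200-individual demo pipeline. The acceptance
script simulates the instrument-strength stage at n = 100,000 with 360
variants.

## Known limitations

- The rank-FDR rule with a strict inequality is implemented as specified for
  this scan; it is not a general-purpose BH procedure.
- MR-Egger uses plain weighted least squares (no SIMEX correction for
  exposure measurement error).
- The multinomial branch reports no coefficient, matching the scan's
  reporting convention, so effect directions for unordered traits must come
  from follow-up.
- Power formulas cover continuous and binary outcomes only.
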
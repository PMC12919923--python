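# Methods

This note documents the models implemented in `trimed`, the assumptions they
make, the defaults of the synthetic-data generator, and the numerical choices
that were genuinely open.

## Structural model of the synthetic world

All continuous traits are built to unit variance, so every coefficient is a
per-SD effect. With latent confounder $C \sim N(0,1)$:

$$X = g_X + cC + \varepsilon_X,\qquad
  M_k = a_k X + b M_{k-1} + g_k + cC + \varepsilon_k,$$

where $g_X, g_k$ are centered polygenic scores with variances
`h2_exposure`, `h2_mediator`, $c$ = `confounder_strength`, $a_k$ = `beta_xm`,
and $b$ = `beta_mm` (0 by default: independent mediators). The noise
variances are solved analytically from the variance budget (including the
$\mathrm{Cov}(X,C)=c$ and chain cross-terms), so each trait has expected
variance exactly 1; a budget exceeding 1 is a configuration error.

The outcome hazard is constant in time:

$$h(t) = h_0 \exp\Big(dX + \sum_k m_k M_k + cC
          + 0.02\,(\text{age}-55) + 0.69\,\text{male}\Big),$$

with $d$ = `beta_xy_direct`, $m_k$ = `beta_my`. Event times are exponential,
administratively censored at `followup_years`. Because the hazard is
proportional by construction, the Cox log-HR equals the planted coefficient,
and path-tracing gives closed-form estimands:
total $= d + \sum_k m_k\,\partial M_k/\partial X$, indirect $=$ total $-$ d,
proportion mediated $=$ indirect/total. A Monte-Carlo integration of the
interventional hazard ratio over the DAG reproduces these within 1%
(tested).

### Defaults and what they emulate

| parameter | default | rationale |
| --- | --- | --- |
| `n_individuals` | 100,000 | a large-cohort analysis at desk scale |
| `baseline_hazard`, `followup_years` | 7.3e-4 /yr, 12 y | ~1,400 events per 100,000 — the event count of a registry-linked cancer cohort, at scaled-down denominator; rare enough that log-HR ≈ log-OR |
| `beta_xy_direct`, `beta_xm`, `beta_my` | 0.225, 0.35, 0.40 | total log-hazard 0.365/SD (HR 1.44), a-path 0.35 — magnitudes reported for adiposity → insulin → renal-cancer pathways |
| `h2_exposure`, `h2_mediator` | 0.10 each | instruments with mean F ≫ 10 at the default arm size |
| `gwas_n_*_arm` | 50,000 each | two-sample arms large enough for per-variant genome-wide discovery of 0.2%-variance SNPs |
| `gwas_case_fraction` | 0.053 | the case fraction of a large cancer case-control GWAS |
| `confounder_strength` | 0.2 | enough latent confounding to separate the arms' behaviour without dominating |
| `maf_range` | (0.05, 0.5) | common variants only |
| `ld_block_size`, `ld_rho` | 5, 0.5 | blocks that exercise clumping; set (1, 0) for pre-pruned instruments |

**LD model.** Haplotypes follow a Markov allele-copy process within blocks of
constant MAF: each allele copies its left neighbour with probability
`ld_rho`, else is drawn fresh. This yields adjacent genotype correlation
exactly `ld_rho` (AR(1) decay $\rho^k$, $r^2=\rho^2$ adjacent) and exact HWE,
which a thresholded Gaussian copula would only achieve after tetrachoric
correction. Blocks never straddle the exposure/mediator variant segments, so
cross-trait instruments are in linkage equilibrium by construction.

**GWAS arms.** The two arms draw disjoint individuals from the same world.
Continuous GWAS use exact per-variant OLS after projecting out covariates
(Frisch–Waugh, vectorized). The binary outcome GWAS uses the one-step score
estimator from the covariate-only logistic null model (β = U/V), the
standard fast approximation, accurate for the small per-variant effects a
GWAS sees. Case-control ascertainment is emulated by an intercept set for
the target case fraction; the conditional log-OR is invariant to such
sampling. Residual logistic non-collapsibility biases marginal per-variant
effects by roughly $1/\sqrt{1+0.346\,\sigma^2_{lp}}$ (≈2% here), which is the
dominant — and accepted — approximation in the MR parameter-recovery checks.

**What the generator does not emulate:** realistic human LD maps,
imputation, population stratification, sex-specific genetic architecture,
time-varying traits, competing risks. Passing tests therefore demonstrate
correctness of the estimators and calibration of the machinery under the
stated model, not robustness to those real-data features.

## Cohort arm

- Transforms: `log`, `zscore`, `per_sd`, and inverse-normal rank with the
  Blom offset $c=3/8$ and average ranks for ties (the common convention; the
  choice is recorded in provenance). Values below a detection limit are
  replaced by LOD/√2, counted and logged.
- a-path: OLS of the (transformed) mediator on the per-SD exposure with the
  default adjustment set (age, sex, center, education, smoking, alcohol);
  categorical covariates are dummy-coded; collinear designs raise.
- Risk: Cox proportional hazards via lifelines with Efron tie handling,
  follow-up time as the timescale; the b-path adds the exposure as an extra
  per-SD covariate. Per-SD scaling uses the analysis sample's SD after
  exclusions (complete-case, with dropped-row counts logged — the simplest
  defensible missing-data policy, and flagged as such).
- Matched sets: incidence-density sampling (controls must be at risk at the
  case's event time), exact sex match, age within ±0.5 y by default, without
  replacement; conditional logistic regression by conditional maximum
  likelihood (Newton), with all-concordant sets reported as non-identified
  rather than estimated.

## Genetic arm

- Instrument selection: p ≤ 5e-8 screen, then greedy clumping (accept best
  p; discard same-chromosome variants within 10,000 kb with r² > 0.01). Ties
  in p break by (chromosome, position, id) for determinism. Missing LD for a
  within-window pair counts as r² = 1, so possibly-correlated instruments
  are never retained; pairs beyond the window are kept regardless.
- Harmonization: matching by identifier; swapped alleles flip sign and
  complement the frequency; strand flips resolve through complements;
  palindromic variants are kept only when both frequencies fall outside
  0.5 ± 0.08 (frequencies on opposite sides imply a flip), else dropped with
  reason codes. Harmonization is idempotent and leaves every Wald ratio
  invariant under allele recodings (property-tested).
- Estimators: IVW as WLS through the origin with weights 1/se²_outcome; the
  default is multiplicative random effects (se inflated by
  √max(1, Q/(J−1))) — the usual choice for large instrument sets — with the
  fixed-effect version always available. MR-Egger adds an intercept after
  orienting exposure betas non-negative; its intercept p is the
  unbalanced-pleiotropy test. P-values are two-sided normal throughout
  (large-sample summary-data practice).
- MR-PRESSO: the observed leave-one-out weighted RSS is compared with
  n_sim = 1,000 parametric simulations from the fitted model (both beta
  vectors redrawn); per-variant squared residuals give outlier p-values,
  Bonferroni-thresholded. The seed is explicit; global type-I error is
  calibration-tested.
- Steiger: per-variant r² = t²/(t² + n − 2) on both sides, observation-scale
  for the binary outcome (the liability-scale alternative is noted but not
  used); strict inequality drops. Default sensitivity order is
  harmonize → Steiger → PRESSO → estimators; the order is configurable since
  no convention fixes it.
- MVMR: weighted multiple regression without intercept on the K
  exposure-beta columns; conditional instrument strength per exposure is the
  weighted residual Q of its beta column regressed on the others divided by
  J − K + 1 (reduces to mean F when K = 1); conditional F < 10 flags the
  estimate weak, and mediation results can be suppressed ("not calculated")
  on that flag. An all-zero exposure column is dropped with a warning so the
  remaining system degrades to univariable IVW.

## Mediation and triangulation

The indirect effect is a·b with the a-path linear (exposure → mediator) and
the b-path on the log-risk scale adjusted for the exposure (Cox in the
cohort arm; MVMR in the MR arm). The Sobel se assumes independent paths —
exact in two-sample MR, an approximation in the cohort arm (one sample is
reused), which is why a Monte-Carlo product CI is offered as a cross-check.
The direct effect is reported both as the mediator-adjusted exposure
coefficient and as total − indirect; the product-method indirect is primary.
The proportion mediated is indirect/total on the log-risk scale (never the
risk-difference scale), with a first-order delta CI treating the inputs as
independent; out-of-range values are flagged, never truncated.

Eligibility for mediation requires direction agreement *and* p < alpha in
both arms (alpha 0.05 by default, configurable; no multiple-testing
correction across mediators by default, Bonferroni available). Note that
with two-sided tests and independent arms the null eligibility rate is
alpha²/2 — the factor ½ is the probability that two independent null signs
agree. Pairwise mediator relations reuse the same machinery for every
ordered pair, with Steiger filtering on the MR side so downstream-trait
variants cannot serve as instruments for an upstream trait.

## Numerical choices and limitations

- Determinism: every stochastic routine takes a seed; the pipeline spawns
  independent substreams for architecture, cohort, each arm, the matched
  sets and the LD reference panel, so arms are disjoint and reruns are
  byte-identical (the manifest records seed, config hash and checksums).
- Report tables round floats to 6 significant digits; `summary.json` keeps
  full precision.
- Problem sizes used in the validation suite (replicate counts of 100–2,000,
  cohorts of 10⁴–10⁵, arms up to 5×10⁴) were chosen as the smallest worlds
  in which the targeted properties are statistically decidable; the
  generator scales beyond them.
- Known limitations: variant matching is by identifier only (no
  chromosome:position fallback) — adequate for the controlled identifiers
  here, a documented gap for real data; no proxy-SNP lookup, indels or
  reference-panel handling; no weighted-median/mode estimators or
  correlated-instrument IVW; no exposure–mediator interaction or
  multiple-mediator joint decomposition.
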
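# trimed

Triangulated mediation analysis for obesity-related risk factors and rare
disease outcomes: a parallel **cohort arm** (direct risk-factor assessment in
longitudinal data) and **genetic arm** (two-sample Mendelian randomization on
GWAS summary statistics), joined by a concordance gate and product-method
mediation.

## The scientific problem

Excess adiposity (high BMI) is an established cause of several cancers, renal
cancer among them, but the circulating factors that *transmit* that risk —
insulin, lipid fractions, blood pressure, sex-hormone binding globulin — are
uncertain. Two study designs give complementary, differently-biased answers:

- **Cohort analysis** regresses each mediator on measured BMI (a-path) and
  fits Cox proportional-hazards models of disease on each mediator (b-path);
  it is statistically efficient but vulnerable to residual confounding.
- **Two-sample MR** replaces measured traits with genetically proxied ones:
  per-variant effects $(\hat\beta_{Xj}, \hat\beta_{Yj})$ from non-overlapping
  GWAS give Wald ratios $\hat\beta_{Yj}/\hat\beta_{Xj}$, pooled by the
  inverse-variance-weighted (IVW) estimator
  $\hat\theta_{IVW} = \sum_j w_j \hat\theta_j / \sum_j w_j$,
  $w_j = \hat\beta_{Xj}^2/\mathrm{se}(\hat\beta_{Yj})^2$; it is immune to
  classical confounding but vulnerable to pleiotropy and weak instruments.

A mediator is taken seriously only when both arms agree in direction and
significance (**triangulation**). For eligible mediators the proportion of
the BMI effect transmitted is estimated by the **product method**: indirect
effect $= a\cdot b$ with Sobel standard error
$\sqrt{a^2\mathrm{se}_b^2 + b^2\mathrm{se}_a^2}$, and proportion mediated
$= ab/\theta_{total}$ on the log-risk scale.

Because the real data behind such analyses (national biobanks, consortium
GWAS) are access-controlled, the package ships a first-class synthetic-data
generator with a known exposure → mediator → outcome DAG — polygenic
instruments, LD blocks, a latent confounder, covariates, a rare exponential
survival outcome and disjoint GWAS arms — so every stage can be validated
against closed-form ground truth.

## What is in the box

| module | contents |
| --- | --- |
| `trimed.simulate` | `SimulationConfig`, `SimulatedWorld`, genotype/trait/GWAS-arm generation, nested case-control matching |
| `trimed.sumstats` | GWAS-SSF-like I/O, p-value screen + greedy LD clumping, allele harmonization, instrument F statistics |
| `trimed.mr` | Wald ratio, fixed/random IVW, MR-Egger, Cochran's Q, MR-PRESSO, Steiger filtering, multivariable MR with conditional F |
| `trimed.cohort` | trait transforms (log, inverse-normal rank, z-score), LOD/√2 imputation, a-path linear models, Cox models (lifelines, Efron ties), conditional logistic regression |
| `trimed.mediation` | product-method indirect effects, Sobel and Monte-Carlo CIs, proportion mediated with delta-method CI |
| `trimed.triangulate` | concordance gate, pairwise mediator relations, pipeline orchestration |
| `trimed.config` / `trimed.report` / `trimed.cli` | YAML config, deterministic TSV/JSON report writers with a run manifest, `trimed` console script |

## Worked example

```python
from trimed.config import PipelineConfig
from trimed.triangulate import run_pipeline
from trimed.report import mediation_table

cfg = PipelineConfig()            # default synthetic world, seed 0
bundle = run_pipeline(cfg, seed=1)
print(bundle.risk_table[["term", "hr_cohort", "or_mr", "n_events"]])
print(mediation_table(bundle)[["framework", "proportion_mediated"]])
print("truth:", bundle.truth.total_log_effect, bundle.truth.proportion_mediated)
```

Output (seed 1):

```
       term  hr_cohort     or_mr  n_events
0       bmi   1.457252  1.436940      1567
1  mediator   1.705880  1.531544      1567
  framework  proportion_mediated
0    cohort             0.458022
1        mr             0.338281
truth: 0.365 0.3835616438356164
```

Reading: the default world plants a total BMI → disease log-hazard of 0.365
per SD (HR 1.44) with 38% of it flowing through the mediator. The cohort arm
estimates HR 1.46, the genetic arm OR 1.44; the mediator passes the
concordance gate in both arms and the two frameworks bracket the true
proportion mediated (0.46 and 0.34 around 0.38). The cohort numbers sit
slightly high because the default world deliberately plants a latent
confounder that only the MR arm is immune to.

The same run from the shell:

```sh
trimed run --config my_config.yaml --out results/ --seed 1
```

writes `risk.tsv`, `bmi_mediators.tsv`, `triangulation.tsv`, `mediation.tsv`,
`edges.tsv`, `dropped_variants.tsv`, a full-precision `summary.json` and a
`manifest.json` (seed, config hash, checksums) that makes the run
reproducible byte-for-byte.

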
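# medimr

Two-sample Mendelian randomization (MR) mediation analysis for GWAS summary
statistics, built for studies that ask *how much of an exposure's causal
effect on disease flows through intermediate traits* — the motivating case
being education's protective effect on diabetic kidney disease (DKD) and
chronic kidney disease (CKD), mediated by cardiometabolic traits such as BMI,
waist-to-hip ratio, blood pressure, glycaemic traits, smoking and type 2
diabetes.

It is aimed at genetic epidemiologists who work with published summary
statistics rather than individual-level genotypes: everything operates on
(SNP, effect allele, beta, SE) tables.

## What it computes

**Core decomposition (two-step MR).** With instruments for the exposure and
for each mediator,

- total effect: `theta_total` = IVW estimate of exposure → outcome,
- step 1: `theta_1` = IVW estimate of exposure → mediator,
- step 2: `theta_2` = mediator → outcome, either univariable IVW or the
  mediator's multivariable-MR (MV-IVW) coefficient adjusted for the exposure,
- indirect effect = `theta_1 * theta_2` (product of coefficients),
- proportion mediated = indirect / total,

with first-order delta-method standard errors:
`se(indirect)^2 = theta_2^2 se_1^2 + theta_1^2 se_2^2` and
`se(prop)^2 = se_ind^2/total^2 + ind^2 se_total^2/total^4`.
Binary traits are carried on the log-odds scale throughout; odds ratios appear
only in formatted output.

**Estimator panel** (`medimr.uvmr`, `medimr.mvmr`): Wald ratios, IVW
(fixed / multiplicative random effects), MR-Egger, weighted median
(bootstrap SE), profile maximum likelihood, constrained ML with BIC model
averaging (cML-MA), a GSMR-style estimator with HEIDI-outlier removal, MV-IVW
and MVMR-Egger.

**Diagnostics** (`medimr.sensitivity`): Cochran's Q, MR-Egger intercept,
MR-PRESSO (global / outlier / distortion), radial-MR outliers (per-SNP Q
contributions summing exactly to Cochran's Q), Steiger directionality
filtering, per-SNP and conditional F-statistics (F > 10 adequacy bound).

**Genome-wide follow-up**: Bayesian colocalization with Wakefield approximate
Bayes factors and H0–H4 posteriors (`medimr.coloc`), SMR at the top cis-eQTL
with the HEIDI linkage test (`medimr.smr`), LD score regression heritability
and genetic correlation with block-jackknife SEs (`medimr.ldsc`), and
FUSION-style TWAS z-scores with BH-FDR control (`medimr.twas`).

**Synthetic data** (`medimr.synthgwas`): generators for instrument-level
mediation scenarios, LD-blocked cis regions with shared/distinct causal
variants, and genome-scale polygenic trait pairs with LD-score-linked
chi-square inflation — so every stage is testable without downloading any
GWAS.

## Worked example

The mediation arithmetic can be run directly on published coefficient tables.
Education (per SD of 4.2 schooling years) on DKD, using the published
estimates bundled in `medimr.examples`:

```python
>>> from medimr import examples
>>> for r in examples.worked_example("DKD"):
...     print(f"{r.mediator:18s} {r.proportion * 100:5.1f}%  "
...           f"(95% CI {r.ci_low * 100:.1f}, {r.ci_high * 100:.1f})")
BMI                 40.1%  (95% CI 26.6, 53.7)
WHR                 39.2%  (95% CI 21.0, 57.5)
T2D                 31.2%  (95% CI 18.7, 43.7)
fasting insulin     20.6%  (95% CI 1.6, 39.6)
SBP                  9.3%  (95% CI 4.9, 13.6)
fasting glucose      8.0%  (95% CI 0.6, 15.4)
DBP                  2.7%  (95% CI 0.4, 5.1)
```

Reading: 40.1% of education's effect on DKD risk (a total OR of 0.5136 per
SD, i.e. a 48.64% risk reduction) is attributable to the path through BMI —
education lowers BMI by 0.2942 SD, and each BMI SD multiplies DKD odds by
2.4821.

The same machinery runs end-to-end from summary-statistics files:

```sh
medimr simulate --kind mediation --seed 3 --out sim/
medimr mediate --exposure sim/exposure.tsv --mediator sim/mediator.tsv \
               --outcome sim/outcome.tsv --step2 mvmr_adjusted --out med.json
```

which on this simulated study (true proportion mediated 0.30) prints a
`proportion` of 0.305 with its delta-method CI.

## Layout

| module | contents |
| --- | --- |
| `medimr.sumstats` | data model, reading, allele harmonization, instrument selection (p < 5e-8, clump r² 0.001 / 10 Mb defaults) |
| `medimr.synthgwas` | scenario dataclasses + the three generators |
| `medimr.uvmr`, `medimr.mvmr` | estimator panel |
| `medimr.sensitivity` | heterogeneity / pleiotropy / outlier / strength diagnostics |
| `medimr.mediation` | product of coefficients, proportion mediated, two-step driver |
| `medimr.coloc`, `medimr.smr`, `medimr.ldsc`, `medimr.twas` | regional and genome-wide follow-up |
| `medimr.pipeline` | mediator screening workflow + report bundle |
| `medimr.examples` | published coefficient tables and the worked example |
| `medimr.cli` | `medimr` command-line entry points |

See `docs/methods.md` for the statistical models, assumptions and numerical
choices.
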
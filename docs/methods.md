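# Methods

## Data model and harmonization

All estimation consumes a *harmonized set*: J SNPs whose effects on K
exposures and one outcome are expressed per copy of a shared effect allele.
Harmonization takes the first exposure's alleles as the reference
orientation; swapped alleles flip the beta sign (and replace eaf by 1 − eaf),
strand flips (A↔T, C↔G) are resolved by complementing before matching, and
palindromic SNPs are kept only when both tables report an allele frequency
with `min(eaf, 1 − eaf) < 0.42`, with the orientation inferred by
minor-allele concordance; otherwise they are dropped with reason
`palindromic_ambiguous`. Tables intersect on rsID, not position, matching
summary-statistics practice. Binary-trait effects live on the natural-log
odds scale everywhere inside the package; odds ratios are computed only when
formatting.

Instrument selection keeps SNPs at p < 5×10⁻⁸ and greedily clumps by
ascending p-value, discarding SNPs within 10,000 kb of a kept SNP on the same
chromosome or with r² > 0.001 against a kept SNP when an LD matrix is
supplied. These are the field-standard settings; published analyses rarely
state theirs, so all three are arguments.

## Estimators

With per-SNP exposure effect b_Xj (SE σ_Xj) and outcome effect b_Yj (SE σ_Yj):

* **Wald ratio** β̂_j = b_Yj/b_Xj with first-order SE σ_Yj/|b_Xj| (a
  second-order option adds b_Yj²σ_Xj²/b_Xj⁴).
* **IVW** is the zero-intercept weighted regression of b_Y on b_X with
  weights σ_Y⁻². The default inference is multiplicative random effects: the
  fixed-effect SE times max(1, √(Q/(J−1))). Fixed effects are an option.
* **MR-Egger** adds a free intercept after orienting every SNP so b_Xj ≥ 0;
  the intercept estimates average directional pleiotropy. Inference is t
  with J−2 df and the same inflation floor.
* **Weighted median** interpolates the inverse-variance-weighted percentile
  function at 0.5; its SE is the SD over 1,000 seeded parametric resamples of
  (b_X, b_Y). Consistent while valid instruments carry > 50% of the weight.
* **Maximum likelihood** treats each SNP's true exposure effect ξ_j as a
  nuisance parameter of a bivariate normal model; profiling ξ_j analytically
  leaves the one-dimensional objective ½Σ(b_Yj − θb_Xj)²/(σ_Yj² + θ²σ_Xj²)
  (no log-variance term arises because the SEs are fixed). The SE is the
  inverse root of the numerical second derivative at the optimum.
* **cML-MA** minimizes the same objective while allowing exactly K SNPs a
  free pleiotropy term (equivalently, excluding the K largest standardized
  residuals), for K = 0..J−2, by coordinate iteration with oscillation
  fallback to the best visited configuration. Models are combined with
  weights ∝ exp(−BIC/2), BIC(K) = 2·nll + K·log J, and the model-averaged
  variance adds the between-model spread to the within-model variance. With
  a log J penalty the K = 0 weight on all-valid data is bounded near
  (Σ_K J^(−K/2))⁻¹ — about 0.78 at J = 20 — which is why the tests assert the
  argmax rather than a dominance threshold. It does not rely on InSIDE. The
  data-perturbation variant (model averaging over resampled datasets) is not
  implemented.
* **GSMR (clumped-instrument form)** iterates the ratio-scale estimate with
  weights [(σ_Yj² + θ²σ_Xj²)/b_Xj²]⁻¹ that carry the exposure sampling error,
  removing any SNP whose standardized deviation from θ has p < 0.01
  (HEIDI-outlier) until stable. It requires at least 10 instruments and, since
  inputs are clumped, uses no LD correlation matrix.
* **MV-IVW / MVMR-Egger** regress b_Y on the J×K exposure-effect matrix
  (weights σ_Y⁻²), without/with an intercept; MVMR-Egger orients rows on a
  chosen exposure (default: the mediator under test). SE inflation uses
  max(1, √(Q/(J−K))) and, for Egger, J−K−1 df. With K = 1, MV-IVW reproduces
  univariable IVW exactly.

## Diagnostics

Cochran's Q uses first-order ratio SEs against the fixed-effect IVW estimate.
The radial transform (x = √w, y = β̂√w, w = (b_X/σ_Y)²) gives per-SNP Q
contributions that sum to Cochran's Q exactly; SNPs exceeding the χ²(1)
critical value at α = 0.05 are outliers (first-order weights only; modified
second-order weights are not implemented). MR-PRESSO builds the null of the
leave-one-out weighted residual sum from parametric draws b'_X ~ N(b_X, σ_X²),
b'_Y ~ N(θ̂₍₋ⱼ₎b_X, σ_Y²) (default 1,000, seeded); per-SNP outlier p-values
are Bonferroni-adjusted, and the distortion test compares the
outlier-corrected IVW shift against removals of random same-size SNP subsets.
Because the null redraws exposure effects around their observed values the
global test is slightly conservative unless θ²σ_X² ≪ σ_Y²; the calibration
suite therefore runs in that strong-instrument regime. Steiger filtering
recovers per-SNP variance explained from the F-statistic, r² = F/(F + n − 2)
— usable without allele frequencies (an eaf-based variant would be a
straightforward extension) — and drops a SNP when the outcome r² exceeds the
exposure r² with a significant Fisher-z test. Conditional F for exposure k is
the weighted residual sum from regressing its instrument effects on the other
exposures' effects, divided by J − K: a practical proxy for the
Sanderson–Windmeijer statistic, gating the screen at F ≥ 10.

## Mediation

The two-step decomposition multiplies the exposure→mediator estimate by the
mediator→outcome estimate and divides by the total effect. Both second-step
variants are computed: univariable IVW on the mediator's instruments, and the
mediator's MV-IVW coefficient adjusted for the exposure. The univariable
variant is the default for reproducing published proportion tables (it is the
one that reproduces them arithmetically); the MVMR-adjusted variant is the
structurally correct one when mediator instruments overlap the exposure's
pathways, and it is what the parameter-recovery tests exercise. Delta-method
SEs treat the two factors — and the indirect and total effects — as
independent, which holds across cohorts in a two-sample design but ignores
the shared outcome GWAS; a bootstrap alternative over the instrument sets
would tighten this and is left out of scope. Binary mediators stay on the
log-odds scale and carry a non-collapsibility caveat flag instead of any
rare-disease conversion. Percent risk change is formatted as
(1 − exp(θ))·100 to two decimals.

The screening pipeline applies sequential gates per candidate mediator —
step-1 significance, step-2 significance, conditional F ≥ 10, MVMR
significance, all at two-sided α = 0.05 with no multiplicity correction
(a BH option exists in config) — and the first failed gate fixes the
decision. Outlier removal (union of PRESSO and radial flags) and
re-estimation run at most twice to guarantee termination.

## Colocalization, SMR/HEIDI, LDSC, TWAS

**Colocalization** enumerates single-causal-variant configurations with
Wakefield log approximate Bayes factors, log ABF = ½[log(1 − r) + r z²],
r = prior_sd²/(prior_sd² + se²), prior SD 0.15 for quantitative and 0.2 for
binary traits. Hypothesis sums are accumulated by log-sum-exp (stable beyond
|z| = 40); priors default to p1 = p2 = 1e-4, p12 = 1e-5 and PPH4 > 0.8 is the
strong-evidence convention. No multi-causal extension.

**SMR** instruments expression with the top cis-eQTL (required p < 5e-8):
T_SMR = z_g²z_e²/(z_g² + z_e²) ~ χ²(1), se = |β_SMR|/√T. **HEIDI** compares
the SMR ratio at surrounding SNPs (eQTL p < 1.6e-3, r² with the top SNP in
[0.05, 0.9], at most 20, the cited tool's defaults) with the top-SNP ratio;
the covariance of the differences follows from the delta method with
LD-induced correlations, and the quadratic-form p-value uses Satterthwaite
moment matching on the eigenvalues of the correlation of d (Davies/Imhof
would be exact; the approximation errs by at most a few percent in the tail
at these dimensions). Fewer than four candidates skips the test, recorded
with a reason.

**LDSC** regresses χ² on LD scores (slope·M/n = h²) and z₁z₂ on LD scores
(slope·M/√(n₁n₂) = genetic covariance), with one weight update
1/[ℓ(1 + n·h²ℓ/M)²] from an initial unweighted fit and free intercepts (the
z-product intercept absorbs sample overlap). rg = gencov/√(h²₁h²₂); SEs come
from a 200-block delete-one jackknife applied to the full ratio. Negative
fitted h² is returned flagged, not truncated; rg beyond ±1.25 is flagged.
Observed-scale only; no liability conversion, no partitioned heritability.

**TWAS** computes z = (wᵀz_GWAS)/√(wᵀ·LD·w) from pre-trained expression
weights (training is out of scope; weights are inputs), repairs a non-PSD LD
matrix by eigenvalue clipping before failing, and controls gene-level FDR by
Benjamini–Hochberg (statsmodels) at 0.05. Shared susceptibility genes across
traits are reported by set intersection.

## Synthetic data: what it emulates and what it does not

`MediationScenario` simulates summary statistics directly (never genotypes —
every consumer is summary-level): instrument effects γ_j ~ N(0, 0.02²) for
the exposure, a mediator effect θ_EM·γ_j, an outcome effect
θ_dir·γ_j + θ_MY·θ_EM·γ_j + α_j, and observed betas with SE = 1/√n (allele
frequency absorbed into the constant; eaf ~ U(0.05, 0.95) recorded for
palindrome/Steiger logic). Pleiotropy α_j is zero for valid SNPs and
N(pleio_mean, pleio_sd²) with tunable correlation to γ_j (InSIDE violation)
otherwise. The mediator additionally carries its own instrument block
(default 100 SNPs, effects N(0, 0.02²), zero exposure effect, outcome effect
θ_MY·δ): without mediator-specific instruments the second step of two-step MR
is not identified, since every mediator instrument would also open the direct
exposure path. Defaults — 100 + 100 instruments, n = 300,000 per trait,
θ_EM = 0.3, θ_MY = 0.5, θ_dir = 0.35 (true proportion mediated 0.30) — mirror
a large-consortium design with mean instrument F ≈ 120. Instruments are
simulated LD-independent (one per chromosome), as clumped instruments are;
LD appears only in the regional generator (AR(1), Σ_ij = ρ^|i−j|, marginal z
~ MVN(Σλ, Σ)) and implicitly in the LD-score generator, whose per-SNP
(z₁, z₂) second moments follow the LDSC model exactly.

What the generators do **not** emulate: realistic minor-allele-frequency
spectra, genome-wide LD maps, winner's-curse selection of instruments,
population stratification, and real LD-score distributions (a gamma shape is
used). Passing tests therefore demonstrate correctness of the estimators and
their calibration under their stated sampling models, not robustness to
those real-data complications.

## Numerical choices and degenerate inputs

One-dimensional likelihood optimizations use Brent's method bracketed around
the fixed-effect IVW start; observed information comes from a central second
difference with step 1e-5·max(|θ|, 1). SE inflation factors are floored at 1
everywhere. Empirical p-values use the (r + 1)/(n + 1) convention, so they
are never zero. Zero exposure effects drop the SNP with a reason; a zero
total effect makes the proportion mediated an explicit error rather than a
NaN; single-SNP regions flag the H3 term as degenerate; constant LD scores
raise a degenerate-design error; non-PSD covariance matrices are repaired to
the nearest PSD matrix with a warning flag. All simulation and resampling
SEs (weighted median bootstrap, MR-PRESSO, generators) are pure functions of
an explicit integer seed.

## Problem sizes

The test suite's simulation studies use the sizes at which the checked
quantities stabilize: 500 replicates for the Egger-intercept and MR-PRESSO
calibration suites (binomial SE ≈ 1% at a 5% rate), 300 for HEIDI, 100
regions for the colocalization detection/separation rates, 40,000 SNPs and
200 jackknife blocks for LDSC recovery, and J = 100 + 100 instruments for
mediation recovery.

## Known limitations

Proportion-mediated CIs are symmetric normal approximations and can cross 0
or 1 for weak totals. Multiple mediators are decomposed one at a time;
overlapping pathways mean proportions need not sum to one. The GSMR form
omits LD between instruments by construction. LDSC is single-iteration
weighted and observed-scale. HEIDI's Satterthwaite tail is approximate.
Binary-mediator products of log-odds coefficients inherit non-collapsibility
and are flagged, not corrected.
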
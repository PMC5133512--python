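# Methods

## The problem

Antihypertensive response varies between people, and part of that
variation is genetic: a variant can blunt (or amplify) the blood-pressure
drop that medication produces. Two testing strategies are in common use
for such gene–exposure interactions in GWAS-style scans:

* **Interaction model** — one mixed model per SNP,

  SBP = α + β_SNP·X_SNP + β_Med·X_Med + β_Int·X_SNP·X_Med + β_C·X_C + g + e,

  with a Wald 1DF test of β_Int and a Wald 2DF joint test of
  (β_SNP, β_Int) using their estimated 2×2 covariance block.

* **Med-diff** — the SNP main effect is fit separately in the medicated
  and unmedicated strata (each its own mixed model), and the stratum
  difference is tested with

  Z = (β₁ − β₀) / √(SE₁² + SE₀² − 2·r·SE₁·SE₀) ~ N(0,1),

  where r is the Spearman rank correlation of the stratified effect
  estimates across SNPs (computed per chromosome per replicate by
  default), guarding against cross-strata correlation of estimates.
  The 2DF joint test is z₁² + z₀² ~ χ²(2).

In family data both approaches sit on a linear mixed model with a
polygenic random effect g ~ N(0, σ_a²·R), R the pedigree numerator
relationship matrix (twice the kinship coefficient; the recursive tabular
method, so inbreeding is handled by the recursion rather than assumed
absent), and e an error term whose variance may differ by medication
status. The package evaluates the two approaches by simulation:
effect-size recovery at causal SNPs (TPP-style experiments) and
false-positive proportions at null SNPs (FPP experiments).

## The synthetic study

The generator emulates a family study of ~20 extended Mexican-American
pedigrees with a simulated SBP phenotype and medication exposure:

* **Pedigrees.** Default template: 3 generations per family — a founder
  couple, 4 children who each marry an entering founder spouse, and 11
  grandchildren per couple. That gives 54 members per family, 1,080
  individuals and 120 founders in 20 families, matching the target of
  ~1,060–1,080 individuals with ~117 founders. Sibship sizes and
  generation count are configurable.
* **Genotypes.** Gene dropping: founders Binomial(2, MAF) under
  Hardy–Weinberg, children receive one allele from each parent; SNPs are
  independent (no LD) unless the block-copy option is used. Dosages are
  integers, so minor-allele counts are exact; externally supplied
  fractional dosages are rounded to nearest before counting. One genotype
  panel is shared by all phenotype replicates.
* **Medication.** Independent Bernoulli with prevalence 0.327 per
  replicate (an optional "indication" mode medicates the top fraction of
  a latent pre-treatment SBP, off by default). The treatment effect is
  β_Med = −6.2 mm Hg.
* **Interaction.** Carriers of a designated SNP are non-responders:
  β_Int = +6.2 mm Hg, so a medicated carrier's expected benefit is
  exactly zero. The default carrier-nonresponse scenario places the
  causal SNP at MAF 5.4% (chr7:99457605); MAF 0.1% and 0.8% variants of
  the same locus are available. The strong-main-effect scenario uses
  MAF 2.7% with β_SNP = −9.91 mm Hg per allele and no interaction
  (chr3:48040283).
* **Trait.** SBP = 135 + 0.4·age − 3·I(female) + genetic terms +
  β_Med·Med + g + e, with ages truncated-normal (mean 48.1, SD 14,
  range 18–101), 58% female among the in-family births,
  σ_a² = 54.3 mm Hg² (total variance ≈181 mm Hg², heritability 0.30), and
  residual variances 119.0 (unmedicated) / 142.8 (medicated) mm Hg²
  (ratio 1.2 with the prevalence-weighted mean equal to the homogeneous
  126.7). The total variance of 181 is derived from the
  strong-main-effect SNP explaining 2.87% of variance
  (2·0.027·0.973·9.91² ≈ 5.16 mm Hg²); the age/sex/intercept effects and
  the 1.2 heteroscedasticity ratio are the package's own choices
  (configurable) since only their existence, not their size, is part of
  the emulated design.
* **Ancestry.** Population structure is adjusted as in founder-PC
  practice: LD pruning (greedy in position order, r² ≤ 0.2) among
  founders, PCA of centered/scaled founder dosages, projection of all
  individuals through the fixed founder means and loadings, top 5 PCs as
  covariates. The simulated sample is a single population, so the PCs
  act as (harmless) noise covariates; the two-population behaviour of
  the PCA itself is exercised in the test suite.

What the generator does **not** emulate: sequence-level data, LD beyond
the optional block copies, genotype imputation, longitudinal phenotypes,
or confounding by indication (off by default). Passing tests therefore
show that the statistics behave as designed under a clean family-study
data-generating process — not that they are robust to imputation error or
real-world LD.

## Mixed-model fitting

Variance components (σ_a², per-group σ_e²) are estimated by REML;
fixed effects by GLS at the optimum with covariance (XᵀV⁻¹X)⁻¹,
V = σ_a²R + D. The optimizer is bounded L-BFGS-B on log-variances with
three deterministic starts (heritability 0.3, 0.05, 0.7), relative
log-likelihood tolerance 1e−6, at most 200 iterations; components are
floored at 1e−10 so V stays invertible (a component at the floor still
counts as converged). Non-convergence is a first-class reported outcome,
not an exception: scans emit the row with `converged=False` and a reason,
so convergence denominators are reproducible. A SNP that is monomorphic
(MAC < 2) in the analyzed rows, or collinear with its interaction term,
is reported as non-converged with a degenerate-design reason.

Because the families are disjoint, R — and hence V — is block diagonal;
the implementation batches equal-sized family blocks into stacked
Cholesky/solve calls, which makes exact REML cheap even genome-scan-wide.
ML log-likelihoods are stored alongside REML (evaluated at the REML
component estimates); the residual-heterogeneity LRT uses REML by
default, which is valid because both models share fixed effects. The
default residual model for Model 1 is heterogeneous by medication status,
with the LRT always available to report.

Two scan modes:

* **scan** (default) — variance components estimated once per replicate
  under the covariates-only model (including the medication main effect;
  per stratum for med-diff) and held fixed per SNP; each SNP then reduces
  to a small whitened least-squares problem. Used for the
  false-positive-calibration experiments and the 200-replicate
  interaction-recovery experiment.
* **exact** — full per-SNP (per-stratum) REML. Used for causal-SNP
  effect-recovery analyses (the strong-main-effect experiment).

Under the null the two modes are equivalent in distribution; GLS
estimates are unbiased under either, so the choice trades a second-order
efficiency refinement against a large constant factor in runtime.

## Evaluation

* **TPP** — fraction of converged replicate tests at a causal SNP with
  p < α (α = 0.05), Wilson 95% score interval (Clopper–Pearson by flag).
* **FPP** — SNP×replicate tests pooled per MAF bin (default bin edges
  0.001/0.01/0.05/0.1/0.2/0.5; a per-replicate-averaged variant is
  provided), after excluding every SNP within the closed window
  ±500 kb of a simulated effect locus — for a causal SNP at
  chr7:99,457,518 the excluded interval is exactly
  chr7:98,957,518–99,957,518, endpoints inclusive.
* **Med-diff convergence** requires both stratum fits; a SNP may
  therefore converge for the interaction model but not for med-diff,
  which is the expected asymmetry between the approaches.
* **Analytic power** replaces an external calculator with the standard
  noncentral chi-square form: for the 1DF interaction,
  λ = n_eff·β²·2p(1−p)·q(1−q)/σ²_e (binary exposure of prevalence q,
  additive coding, G ⊥ E); for 2DF main-effect testing
  λ = n_eff·β²·2p(1−p)/σ²_e against χ²(2). The effective sample size
  uses the 80% convention (n_eff = round(0.8·n), e.g. 1,061 → 849) to
  discount the non-independence of relatives.

## Problem sizes and numerical choices

The packaged experiments use 200 replicates for interaction/medication
effect recovery and prevalence calibration, 100 replicates for
main-effect recovery and 2DF power, and 50 replicates × 400 null SNPs
for each false-positive experiment (MAF uniform on 1–50% for the med-diff
calibration; 0.5–5% for the low-MAF interaction-model check). These sizes
give Monte-Carlo standard errors a small fraction of the effects under
study (≈0.2 mm Hg on a 6.2 mm Hg effect; ≈0.15 percentage points on a 5%
proportion pooled over ~20,000 tests) while keeping each experiment in
the minutes range on one core.

Tie-breaks and degenerate inputs: LD pruning keeps the earlier SNP in
position order and drops monomorphic SNPs first; Spearman r falls back to
0 (logged in the result rows) when fewer than 2 SNPs have converged
stratified estimates in a scope; the med-diff variance guard rejects
SE_Diff² ≤ 0 (possible only at r → 1 with equal SEs) as non-convergence;
empty FPP bins are reported with n = 0 rather than erroring; the
heterogeneity LRT clips its statistic at 0.

## Design choices that were genuinely open

* The printed form of the interaction-model 2DF covariance matrix repeats
  Var(β_SNP) on both diagonal cells in some descriptions; the Wald form
  requires Var(β_Int) in the bottom-right cell, and that is what is
  implemented.
* Medication is assigned independently of SBP by default; the FPP/TPP
  logic does not require confounding by indication, so the indication
  mode is opt-in.
* PCA scales founder dosages to unit variance (common GWAS practice); a
  toggle disables scaling.
* Spearman r is computed per chromosome within each replicate, over SNPs
  passing filters with converged stratified fits; genome-wide scope by
  flag.
* The Z difference test is two-sided against the standard normal.
* Genotype coding is additive dosage of the counted allele; the
  interaction column is the product dosage × medication indicator.

## Known limitations

* Single polygenic random effect only; no GLMM/binary traits, no score
  tests, no robust (sandwich) standard errors.
* Wald tests at very low minor-allele counts inherit the usual
  small-sample behaviour of Wald statistics; the MAC ≥ 2 filter is the
  only guard, as in the emulated design.
* The med-diff 2DF joint test, following its published form, does not
  correct the cross-strata correlation that the 1DF test corrects.
* FPP pooling treats SNP×replicate tests as exchangeable within a MAF
  bin; dependence between SNPs on one replicate is ignored (the Wilson
  interval is slightly narrow if that dependence is strong).
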
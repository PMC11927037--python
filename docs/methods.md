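# Methods

## Model and assumptions

The package analyses three summary-statistics panels — per-gene cis-eQTL
associations (exposure), a mediator-trait GWAS and an outcome-trait GWAS —
under the standard instrumental-variable assumptions of Mendelian
randomization: instruments associate with the exposure, affect the outcome
only through it (no horizontal pleiotropy, relaxed by the Egger and
weighted-median estimators), and share no confounder with the outcome. All
effects are treated as linear and homogeneous; case-control effects are on
the log-odds scale. Exposure and outcome samples are assumed
non-overlapping, so sampling errors of β̂_exp and β̂_out are independent.

The causal structure of interest is a chain: gene expression → mediator →
outcome, plus a possible direct gene → outcome edge. The decomposition is
the usual product-of-coefficients one: total = direct + a·b, with a the
gene→mediator and b the mediator→outcome effect.

## Estimators

* **SMR / HEIDI.** The SMR statistic at the top eQTL variant is
  T = z²_eQTL z²_GWAS/(z²_eQTL + z²_GWAS), referred to χ²(1); the reported
  SE of b_xy is |b_xy|/√T. HEIDI selects variants with eQTL p < 1.57·10⁻³
  and r² to the top variant in [0.05, 0.9] (at most 20, at least 3;
  defaults of the originating tool, exposed in `HeidiSelection`), forms the
  Wald-ratio differences d_i against the top variant, and evaluates
  T_HEIDI = Σ (d_i/sd_i)² against a weighted-χ² null. The weights are the
  eigenvalues of the correlation matrix of the d_i, obtained from the
  first-order (delta-method) covariance of the ratios with LD-r-scaled
  sampling covariances within each study. The null tail is computed by
  seeded Monte Carlo (default 20 000 draws of Σ λ_j z_j²); a Satterthwaite
  two-moment χ² approximation is available as a faster alternative
  (`method="satterthwaite"`).
* **IVW.** Weighted regression of β̂_out on β̂_exp through the origin with
  weights 1/se_out². The multiplicative-random-effects SE multiplies the
  fixed-effects SE by the residual standard deviation, *not floored at 1*
  (so under-dispersed data can yield a smaller SE than fixed effects);
  p-values use the normal approximation. With a single instrument all
  fitters fall back to the Wald ratio with first-order SE se_out/|β̂_exp|.
* **MR-Egger.** Weighted regression with intercept after orienting all
  exposure betas non-negative. Slope and intercept p-values use t(k−2);
  the intercept is the directional-pleiotropy test. The bootstrap variant
  resamples instrument rows (default 1000, seeded) and reports the median
  slope with the empirical SD.
* **Weighted median.** Ratio estimates ordered, inverse-variance cumulative
  weights interpolated at 0.5; SE by parametric bootstrap of
  (β̂_exp, β̂_out) from their reported sampling distributions (default 1000
  draws, seeded).
* **Sensitivity rule.** MR-Egger (bootstrap) when the Egger intercept is
  significant at α = 0.05; otherwise IVW-MRE (the primary method, which
  also covers the significant-heterogeneity case). Pleiotropy takes
  precedence over heterogeneity when both are flagged; the α level and the
  precedence are design choices, exposed in configuration.
* **MVMR.** Pairwise multivariable IVW — one gene plus the mediator per
  fit — by weighted multiple regression through the origin with weights
  1/se_out². The instrument set is the union of the gene's and the
  mediator's clumped instruments present in all three panels. Weights
  ignore the uncertainty of the mediator betas (a known limitation of
  regression-based MVMR: measurement error in the mediator column
  attenuates its coefficient slightly, which is why the fit is used for
  the *direct* gene effect, not to re-estimate b).
* **Mediation.** a is always the IVW-MRE (or single-instrument Wald)
  gene→mediator estimate; b is estimated once from the mediator's own
  instruments and reused for every gene. a and b come from different
  estimation stages and are treated as independent. The product SE defaults
  to the exact product-normal variance (first-order available); the 95% CI
  is the 2.5/97.5% quantile pair of N(a,σ_a²)·N(b,σ_b²).

## Distribution-of-product interval: numerics

The CDF of the product of two independent normals is evaluated by 151-node
Gauss–Hermite quadrature of the conditional normal CDF, integrating over
whichever factor has the larger |mean|/SE so that the conditional CDF of the
other, broader factor varies smoothly across nodes (conditioning on a
narrow factor would put a near-step discontinuity under the quadrature).
Quantiles are found by 96 bisection steps on an interval of ±12 combined
SDs around a·b, vectorized over inputs. Against 10⁷-draw Monte Carlo
quantiles the analytic endpoints agree to well within 0.005 on unit-scale
inputs (asserted in the test suite). The Monte Carlo route (seeded, default
10⁶ draws) is retained both as an independent cross-check and for users who
prefer simulation.

Degenerate inputs: σ_a = σ_b = 0 gives a point interval at a·b; as σ_a → 0
the interval converges to the normal-theory a·b ± z·|a|σ_b (tested at
σ_a = 10⁻⁹). Back-derivation of (a, σ_a) from a reported product and SE
raises an explicit infeasibility error when the reported SE is smaller than
the b-path contribution alone — which happens for legitimately published
rows when b is only available rounded to two decimals; such rows cannot be
decomposed and are excluded from worked-example checks.

## Cascade conventions

* Clumping: greedy by ascending p (ties broken by variant id), discarding
  same-chromosome variants within the full two-sided window (|Δpos| ≤
  window_kb·1000, the PLINK convention) at r² ≥ threshold. Defaults
  p < 5·10⁻⁸, 10 000 kb, r² 0.001. An instrument-less gene is recorded,
  not an error.
* Harmonization: outcome betas aligned to the exposure effect allele with
  sign flips and EAF complementation; strand flips resolved by complement
  matching; palindromic (A/T, C/G) variants dropped when the minor-allele
  frequency exceeds 0.42 or the EAF is missing (policy and threshold
  configurable). The originating study does not state its policy; these
  are the conventions of the standard harmonization tooling.
* Bonferroni: each stage tests at 0.05/n where n is the *realized* survivor
  count of the preceding stage (recorded per stage in the reports, audited
  by tests). Multiplicity is controlled within stages only, mirroring the
  analysis design; no across-stage adjustment is attempted.
* Classification: total-significant → direct-significant → mediation-only
  (95% CI excludes zero) → none. "Significant mediation" is defined by the
  CI, not a p-value, because mediated effects are reported with
  distribution-of-product intervals. The causal direction handed to drug
  triage is the sign of a·b.
* Determinism: every stochastic component (HEIDI null draws, bootstraps,
  Monte Carlo CIs) takes a seed derived from the single config seed;
  identical bundle + config reproduce byte-identical stage reports.

## Synthetic data: what it emulates, and what not

Summary statistics are generated directly (no genotypes): marginal effects
under LD follow β_marg = R·β_causal, and sampling noise is multivariate
normal with covariance D·R·D (D = diag of per-variant SEs). Per-variant SEs
use 1/√(2·maf·(1−maf)·n) for the quantitative eQTL panel and
√(4/(n_eff·2·maf·(1−maf))) with n_eff = 4/(1/n_cases+1/n_controls) for the
case-control panels. MAFs are uniform on (0.1, 0.5).

Default sample sizes emulate the motivating setting: eQTL n = 31 684;
mediator 10 154 cases / 454 764 controls; outcome 216 528 subjects. The
outcome case count is set to 25 (n_eff ≈ 100): the outcome is modelled as a
*rare* complication whose per-gene scan is underpowered relative to the
mediated path — exactly the regime in which mediation-only genes are
detectable and for which the cascade is designed — and this choice also
places the simulated mediator→outcome SE near the reported scale (≈0.3).
With a well-powered outcome GWAS, a gene with a ≠ 0 would have a detectable
total effect a·b and the mediation-only category would be empty by
construction.

Each gene locus is built from `n_instruments` mutually unlinked blocks of 5
variants with AR(1) LD (ρ = 0.8), the causal variant mid-block: clumping at
r² < 0.001 then retains exactly one variant per block, and the HEIDI
selection finds ≥ 4 variants in LD with the top eQTL. Block one carries a
dominant lead eQTL (|β| = 0.5, as cis lead variants typically are); the
other blocks draw |β| ~ U(0.08, 0.20) — all genome-wide significant at the
eQTL sample size. The mediator's own 30 instruments draw
|β| ~ U(0.12, 0.30), strong enough that the weak-instrument attenuation of
IVW (≈ E[se²/β²]) is an order of magnitude below the recovery tolerances.
Knobs: directional/balanced pleiotropy enters the mediator equation at the
causal variants; a heterogeneity multiplier over-disperses the outcome
noise; a per-gene linkage flag adds a mediator-only causal variant inside
the lead block at LD r ≈ 0.7 (the HEIDI alternative).

Not emulated: realistic allele-frequency spectra, imputation noise, sample
overlap between panels (parameter reserved, default 0), trans effects,
multi-gene loci. Passing recovery tests therefore demonstrates correctness
of the estimators and the pipeline logic under the stated generative model,
not robustness to everything real GWAS data can do.

## Problem sizes used in the checks

Worked-example CI checks are deterministic and instantaneous. Oracle
equivalence uses 100 random 50-instrument IVW problems, 200 random loci of
≤ 25 variants for clumping, and a 20-point grid against 10⁷-draw Monte
Carlo for the product-distribution quantiles. Calibration uses 10⁴ null
replicates each for the SMR and Egger-intercept tests and 2000 replicates
for CI coverage; recovery uses 200 simulated studies for the
mediator→outcome effect and four seeded standard scenarios (40 genes total)
for cascade classification. HEIDI operating characteristics use 500 locus
replicates per scenario. These sizes keep every Monte Carlo acceptance
band at least three binomial SEs wide.

## Known limitations

* HEIDI's delta-method covariance is first-order; with very weak top eQTLs
  it underestimates ratio variance (mitigated by the z² > 10 selection
  threshold inherited from the originating tool).
* The IVW-MRE p-value uses the normal approximation; at k ≈ 30 instruments
  its finite-sample size is ≈ 0.06 rather than 0.05 (a t(k−1) reference
  would be exact under homogeneity). The fixed-effects variant is exactly
  calibrated and is what the null-calibration test exercises.
* MVMR weights ignore mediator-beta uncertainty (see above).
* The mediation decomposition treats a and b as independent; a correlation
  parameter is not currently propagated (the two are estimated from
  different instrument sets and different outcome panels, making the
  independence assumption mild here).
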
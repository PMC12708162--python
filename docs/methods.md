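# Methods

## The model

Two-sample MR treats genetic variants as instruments for a modifiable
exposure. A variant j is a valid instrument if it (i) associates with the
exposure, (ii) is independent of confounders of the exposure–outcome
relationship, and (iii) affects the outcome only through the exposure
(exclusion). Under these assumptions each SNP's Wald ratio
β̂ⱼ = β̂ᵧⱼ/β̂ₓⱼ estimates the causal effect, and the package's estimators are
different ways of combining the ratios that trade efficiency against
robustness to violations of (iii):

| estimator | valid when | notes |
|---|---|---|
| IVW (fixed/random) | all instruments valid | most efficient; first-order weights (β̂ₓⱼ/σᵧⱼ)²; random-effects SE × √max(1, Q/(n−1)) |
| MR-Egger | pleiotropy independent of instrument strength (InSIDE) | intercept = mean directional pleiotropy |
| weighted median | < 50% of weight invalid | weights are inverse *delta-method* ratio variances, σᵧ²/β̂ₓ² + β̂ᵧ²σₓ²/β̂ₓ⁴ |
| simple / weighted mode | largest ratio-sharing group valid | KDE argmax, modified-Silverman bandwidth × `bandwidth_factor` |

All CIs use z = 1.959964. Binary-trait effects are log-odds; odds ratios are
exp(β).

Numerical conventions worth knowing:

- **IVW** is the closed-form ratio meta-analysis; the statsmodels WLS
  zero-intercept fit is used in the test suite as an independent oracle, not
  as the implementation.
- **MR-Egger** orients every SNP to a non-negative exposure effect before
  fitting (the intercept is undefined without a sign convention) and uses
  classical weighted-regression inference: SEs scale with the estimated
  residual dispersion σ̂ and p-values use t with n − 2 df. σ̂ is deliberately
  *not* truncated below 1 here — truncation makes the pleiotropy test
  conservative (measured type-I ≈ 3.4% vs 4.2% nominal 5% under the null).
  The truncation-at-1 device belongs to the multiplicative random-effects
  model and is applied where that model is invoked: random-effects IVW and
  the MVMR fit.
- **Weighted median / mode** SEs come from a seeded parametric bootstrap
  (default 1,000 draws) resampling both β̂ₓ and β̂ᵧ from their sampling
  distributions; `n_boot=0` returns the point estimate alone.
- **Mode estimators** evaluate the kernel density on a 512-point grid over
  the ratio range ± 3 bandwidths; with all ratios equal the bandwidth
  degenerates and the common ratio is returned.
- **Cochran's Q / I² / leave-one-out** reuse the IVW first-order weights so
  the diagnostics are internally consistent with the primary estimator.
  I² is clamped to 0 when Q ≤ df and banded mild [0, 25], moderate (25, 50],
  high (> 50). A leave-one-out exclusion is flagged when it flips the
  estimate's sign or moves it by more than one full-set SE (a package
  choice; visual inspection is the field's habit).
- **Steiger direction**: r² on each side is Σ 2·MAF(1−MAF)β̂², direction is
  TRUE iff r²_exposure > r²_outcome, and the p-value is a Fisher-z
  comparison of the implied correlation magnitudes √r² with the two panel
  sizes. Published analyses rarely state their variance formula for this
  test, so exact p-value agreement with any particular report is not
  claimed.
- **Harmonization** aligns the outcome to the exposure's effect allele by
  allele letters (including strand complements), flipping β and EAF where
  swapped. Palindromic SNPs (A/T, C/G) are aligned by allele frequency and
  dropped when either EAF is inside [0.42, 0.58] (ambiguous strand) — common
  MR practice. Indels and multi-allelic records are rejected at ingest.
- **Clumping** is greedy with p-value priority (ties: SE, then SNP id);
  without a pairwise r² lookup it degrades to distance-only pruning
  (r² < 0.001, 10,000 kb defaults). A reference-panel-backed clump is out of
  scope; the optional LD lookup (3-column TSV) covers callers who have one.
- **Instrument strength** uses k = 1 per SNP so that per-instrument
  F summaries (median/min/max) have the shape instrument tables are usually
  reported in; an `overall=True` variant sums R² with k = n_snp. The
  pipeline excludes F < 10 instruments by default (override available).
- **MVMR** pools SNPs significant for any exposure, clumps jointly with the
  best cross-exposure p as priority, aligns all traits to a common effect
  allele, and fits the no-intercept weighted regression. An all-zero
  exposure column is dropped with a warning (its effect reported NaN, and
  the fit then reduces exactly to univariable IVW for the remaining
  exposure); rank deficiency among non-zero columns is an error naming the
  collinear exposures. Per exposure the package reports how many retained
  SNPs are genome-wide significant *for it* — deliberately not the ambiguous
  "number of SNPs" bookkeeping sometimes seen in published MVMR tables, and
  it refuses under-identified designs rather than fitting them.
- **Mediation**: β_M = β_A·β_B exactly. The default SE is the two-term delta
  method √((β_A SE_B)² + (β_B SE_A)²); a three-term variant adding
  SE_A²SE_B² (the exact variance of a product of independent normals) is
  exposed as `se_variant="three_term"`. The two-term default is the variant
  whose CIs are internally consistent with the package's reporting
  conventions and with the published decomposition the acceptance script
  reproduces (whose printed CIs match two-term to < 0.1%, though the
  three-term formula is printed alongside them — the package exposes both
  rather than adjudicating). The proportion-mediated sign rules (direct-
  effect denominator with |·| when β_M and β_C′ disagree in sign, total-
  effect denominator otherwise) are implemented verbatim despite the
  unusual mixed denominators; interpretation is left to the analyst.
  `run_mediation` uses *random-effects* IVW for its univariable stages:
  when the mediator has SNP effects of its own, the exposure→mediator
  ratios are genuinely heterogeneous and a fixed-effect SE would make the
  stepwise significance rule wildly anti-conservative.
- **Headline rule** (pipeline): significant Egger intercept → report Egger;
  else significant Q → random-effects IVW; else fixed-effects IVW. Ties at
  exactly p = α are non-significant. All methods are always reported.

## The synthetic generator

`simulate_two_sample` / `simulate_mediation` draw, per SNP: MAF ~ U(maf_range);
exposure effect γⱼ = |N(0, snp_effect_sd²)| (the effect allele is oriented to
be exposure-increasing, the usual convention for instrument lists — and the
orientation is what makes a directional pleiotropy mean recoverable);
mediator effect γⱼ·β_XM + δⱼ with δⱼ ~ N(0, mediator_snp_effect_sd²);
pleiotropic outcome effect αⱼ ~ N(pleiotropy_mean, pleiotropy_sd²) on a
random `invalid_fraction` of SNPs; outcome effect
γⱼ·β_XO + (γⱼβ_XM + δⱼ)·β_MO + αⱼ. Estimated effects add independent
N(0, se²) noise per GWAS panel with se = 1/√(2·MAF(1−MAF)·N) (standardized-
trait approximation; binary-trait scaling subtleties are not modelled), so
the two-sample (no overlap) structure holds by construction. δⱼ matters:
without mediator-specific effects the exposure and mediator columns of an
MVMR design are proportional up to noise and the direct/indirect split is
unidentifiable — a mediator must bring instruments of its own.
`outcome_snp_fraction` reserves SNPs with γ = 0 and a direct outcome effect
(the outcome's own instruments, needed for a clean reverse-MR null), and
`ld_block_size` packs consecutive SNPs within 100 kb to exercise clumping;
otherwise SNPs are unlinked and > 10,000 kb apart, so clumping is a
pass-through.

What the generator does *not* emulate: LD from a reference panel, winner's-
curse-inducing discovery/replication structure, population stratification,
case-control ascertainment, or individual-level genotypes. Passing tests
therefore demonstrate estimator correctness under the stated model, not
robustness to those real-data complications.

### Defaults and study conditions

Defaults: 100 SNPs, N = 50,000 per panel, maf_range (0.1, 0.5),
snp_effect_sd = 0.1. These make instruments strong (per-SNP F ≈ 200) while
the instruments jointly explain ΣR² ≈ 0.37 of the exposure — large but
physically possible, and safely inside the r² < 1 domain of the Steiger
test.

The Monte-Carlo acceptance checks use conditions chosen from an explicit
error budget *before* the suite was run. Ratio estimators carry a
regression-dilution bias ≈ β·Σσₓ²/Σγ² from noise in the exposure betas; the
recovery tests must keep that bias well inside the 3-MC-SE band
(≈ 3·σᵧ/√(Σγ²·reps)), whose ratio is (β/3)·√(reps·n_snp)·σₓ/√(Var γ). With
200 replicates × 100 SNPs, β = 0.1 and snp_effect_sd = 0.2 put the bias at
≈ 0.3 of the band; Steiger scenarios instead use snp_effect_sd = 0.08 with
β = 0.3 so that ΣR² stays below 1 on both sides. Estimator inputs are always
*screened* instruments (p < 5e-8), as in real analyses — screening also
guarantees the exposure-effect signs are measured without error, which the
Egger orientation step needs. Type-I calibration runs under the global null
(β = 0): with first-order weights, Cochran's Q is inflated by
≈ 1 + β²(σₓ/σᵧ)² when a causal effect is present (a known property of the
weighting, not a bug), so the global null is where "5%" is exactly 5%.
The mediation recovery scenario uses mediator_snp_effect_sd = 0.3 so the
MVMR attenuation from mediator-side measurement noise (≈ σ²/Var δ) is
negligible.

## Known limitations

- **Weighted median under one-sided contamination.** With a directional
  pleiotropy mean on 40% of instruments, the weighted median retains a
  finite-sample bias ≈ Φ⁻¹(0.5/valid-weight-share) × (typical ratio SE):
  the invalid mass pushes the 0.5 weighted quantile into the upper tail of
  the valid cluster. Measured at pleiotropy mean 0.3 on 40% of 100 SNPs:
  weighted-median mean error +0.011 versus IVW's +0.48 — some forty-five-fold
  more robust, exactly the estimator's advertised property, but *not* unbiased:
  because both the bias and the Monte-Carlo SE scale linearly with the ratio
  SE, the bias is ≈ 17 MC SEs at 200 replicates no matter how the sample
  sizes or effect scales are set, and the corresponding strict
  mean-within-3-MC-SE acceptance check fails by construction. The dedicated
  acceptance test documents this honestly rather than relaxing the bound.
- First-order IVW weights ignore exposure-side noise; Q is therefore
  miscalibrated away from the null (see above) and IVW carries the
  regression-dilution term. Second-order or modified weights are not
  implemented.
- No MR-PRESSO outlier removal, contamination-mixture, or robust-regression
  estimators; no MVMR-Egger/median; no proxy-SNP lookup; no LD computation
  from genotype panels; no network access of any kind.
- Reverse MR on data with a true forward effect is intrinsically
  contaminated (the outcome's hits include the causal SNPs); the Steiger
  test, not the reverse estimate, is the directionality check.
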
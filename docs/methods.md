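# Methods

## Design and assumptions

`mrmediate` performs summary-statistics-based causal mediation in two steps.
Step one establishes eligibility: a candidate trait must causally associate
with both the mediator and the outcome (univariable IVW, FDR-controlled) and
must not itself be altered by the mediator (reverse IVW using the mediator's
instruments), because a reciprocal exposure–mediator association invalidates
the decomposition. Step two decomposes the eligible trait's total effect:
the direct effect is the trait's coefficient in a joint multivariable MR fit
of the outcome on trait and mediator, and the indirect effect is the product
β₁·β₂ of the trait→mediator effect and the mediator→outcome effect from that
same joint fit.

The usual instrumental-variable assumptions apply per SNP: association with
the exposure, independence from confounders, and no effect on the outcome
except through the modelled exposures. All estimators assume linear,
homogeneous effects on the scales of the summary statistics. Both the direct
effect and β₂ are read off one joint multivariable fit rather than two
separate fits with swapped covariable roles; this is the simplest
internally consistent decomposition, and it makes total ≈ direct + indirect
hold automatically in the linear model (checked in simulation to within
combined Monte-Carlo error).

## Estimators and standard errors

- **IVW**: closed-form no-intercept WLS with weights 1/se²(β̂_Y). Default SE
  is multiplicative random effects, se_fixed · max(1, √(Q/(J−1))): it never
  undercuts the fixed-effect SE and inflates only under excess
  heterogeneity. Fixed-effects is available via `model="fixed"`. P-values
  are two-sided normal.
- **MR-Egger**: WLS with a free intercept after orienting each SNP so its
  exposure beta is non-negative (the intercept is only identified on that
  orientation). Coefficient SEs multiply the unscaled WLS covariance by
  max(1, residual SD) — the covariance is never shrunk below its
  homoskedastic value on underdispersed data; inference is t with J−2 df.
  Exactly collinear (zero-spread) designs are refused.
- **Weighted median**: ratios sorted ascending, weights β̂_X²/se²(β̂_Y)
  normalized; the cumulative midpoint score S_j = Σ_{i≤j} w_i − w_j/2 is
  interpolated at 0.5 (clamped to the end ratios outside the score range).
  The SE is the SD of the estimate over a seeded parametric bootstrap
  (default 1000 replicates, resampling both betas from their reported
  normals); zero draws of an exposure beta are nudged to the smallest
  positive float rather than dropped so the bootstrap sample size is stable.
- **MR-PRESSO**: the observed statistic uses closed-form leave-one-out IVW
  slopes; the null distribution re-derives those slopes on every simulated
  dataset (vectorised, so the default 1000 simulations cost milliseconds).
  The global p is the add-one Monte-Carlo tail; per-SNP outlier p-values are
  Bonferroni-compared with `outlier_alpha` (default 0.05). If outlier
  removal would leave fewer than two SNPs the corrected estimate falls back
  to the full-sample IVW.
- **Multivariable MR**: no-intercept WLS on the J×K exposure-beta matrix,
  SE scaling as for Egger, t inference with J−K df, and a hard rank check
  (collinear exposure-beta columns raise rather than silently pseudo-invert).
- **Conditional F**: for exposure k, regress its instrument betas on the
  other exposures' betas (weights 1/se_k², no intercept) and divide the
  weighted residual sum of squares by J−K+1. Published variants differ in
  whether cross-trait sampling covariance enters the weights; this
  covariance-free version needs no trait-overlap estimates, is invariant to
  jointly rescaling the target's betas and SEs and to the other exposures'
  units, and reduces at K=1 to the mean per-SNP F.
- **Sobel SE** for the indirect effect: √(β₂²se₁² + β₁²se₂²), the
  first-order delta method. No CI is attached to the proportion mediated by
  default; the proportion is left undefined (not NaN) when |total| is below
  1e−12.

## Harmonization and instrument selection

Effects are aligned to the exposure's effect allele: identical allele pairs
pass through, swapped pairs negate the beta and complement the EAF, strand
complements are resolved via base complementation. Palindromic SNPs (A/T,
G/C) are aligned by allele frequency only when min(EAF, 1−EAF) ≤ 0.30 in
every study — frequencies near 0.5 cannot resolve strand — and dropped
otherwise (or when any EAF is missing). Every intersection SNP is either
retained or listed with a drop reason, so |retained| + |dropped| equals the
intersection size.

Clumping is greedy on p-value: the smallest-p unpruned SNP becomes an index
SNP and removes same-chromosome SNPs within `window_bp` of it (|Δpos| ≤
window, default 10 Mb read as distance-to-index) having r² ≥ 0.001 with it.
Ties break deterministically on (p, chromosome, position, SNP id), making
the output invariant to input row order. LD comes from a precomputed
pairwise table; an absent pair is r² = 0. Instruments must additionally be
genome-wide significant (P < 5×10⁻⁸) and biallelic single-nucleotide
variants (indels are excluded); fewer than 10 survivors raises a typed
`InsufficientInstrumentsError` that screening treats as a trait status, not
a crash. Multivariable instrument sets take the union of each exposure's
significant SNPs, clump on the per-SNP minimum p across exposures (a rule
that is symmetric in the exposures), and require K+2 survivors.

FDR control is Benjamini–Hochberg, applied separately to each screening leg
(trait→mediator, trait→outcome, reverse) across traits; "not
reverse-caused" means the reverse-leg q ≥ 0.05.

## The synthetic generator

`simulate_summary_stats` draws per-SNP effects under the linear structural
model (γ on the exposure, δ on the mediator only, structural coefficients
α, β_M, τ′) and adds cohort-specific Gaussian noise with the analytic SE of
a per-allele coefficient on a unit-variance trait, 1/√(2p(1−p)N). It works
entirely at the summary level: exact for this model, no genotypes. Defaults
encode the intended study conditions — 150 exposure SNPs, 100 mediator-only
SNPs, 50 null SNPs, three non-overlapping cohorts of 200 000, τ′ = 0.2,
α = 0.3, β_M = 0.5, no pleiotropy. MAFs are uniform on (0.05, 0.5);
γ and δ have SD 0.05, which at N = 2×10⁵ gives per-SNP |z| around 14 for a
typical causal SNP, the strong-instrument regime of consortium GWAS, so
significance-based selection introduces negligible winner's-curse bias.
Optional pleiotropy gives a fraction of exposure SNPs a direct outcome
effect η ~ N(η_mean, η_sd) attached to the exposure-increasing allele, so a
nonzero η_mean is *directional* pleiotropy that the Egger intercept should
detect; η assigned independently of allele coding would cancel under
Egger's orientation and be undetectable by design.

`simulate_trait_panel` builds screening fixtures: each trait has its own
causal SNPs, the mediator has its own instruments, and every cohort reports
the full SNP universe. A trait spec's mediator/outcome effects are its
*marginal* per-instrument effects (the quantities the forward IVW legs
estimate), not extra paths on top of an implied mediated path — otherwise a
trait designed as "mediator-associated only" would inevitably associate
with the outcome through the mediator and that status would be
unconstructable. Reverse causation is realized by giving the mediator's
instruments true effects on the trait.

What the generator does not emulate: LD structure (all simulated SNPs are
independent; clumping is exercised with hand-built LD tables), binary
traits (everything is continuous — the liability/log-odds scale of a binary
mediator, and what "proportion mediated" means there, is out of scope),
sample overlap between cohorts, allele-frequency drift between studies
(except under the `palindrome_stress` flag), and missing variants. Passing
tests therefore demonstrate correctness of the estimators and orchestration
under the model's assumptions, not robustness to real-data pathologies such
as correlated instruments or winner's curse at marginal significance.

## Problem sizes and tolerances

Oracle-equivalence tests compare IVW/Egger/weighted-median/MVMR to
independent lstsq and definitional computations at 1e−10 on 100 random
fixtures. Parameter-recovery checks use 200 replicates of the default
configuration (mean total within ±0.01 of 0.35, mean indirect within ±0.01
of 0.15, mean proportion within 3 points of 42.9%, total-effect CI coverage
in [0.92, 0.98]); Sobel type-I uses 500 null replicates (≤ 7% at nominal
5%), MR-PRESSO null calibration 200 replicates of 20 SNPs against binomial
99% bounds, and screening correctness 100 replicates of a six-trait panel
(each designed status recovered in ≥ 90%). The screening panel uses 30 SNPs
per trait and 60 mediator SNPs — enough instruments for near-certain leg
classification while keeping the whole suite fast. The acceptance script
reports the same quantities at slightly smaller replicate counts (150/300/
200/50), all seeded from its `--seed`.

## Known limitations

- No LD-aware (correlated-instrument) IVW; the LD table is used only for
  clumping.
- No MR-RAPS, mode-based, contamination-mixture, or Steiger-filtering
  sensitivity analyses; no MVMR-Egger or Q-minimisation MVMR.
- The conditional-F convention above need not reproduce values computed
  with covariance-weighted variants.
- Proxy-SNP lookup, liftover, GWAS-VCF parsing, and multi-allelic
  decomposition are out of scope; inputs are delimited text tables.
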
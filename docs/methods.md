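# Methods

## Model and assumptions

The package performs two-sample Mendelian randomization on GWAS summary
statistics. A SNP is a valid instrument for an exposure if it is (i)
associated with the exposure, (ii) independent of confounders, and (iii)
affects the outcome only through the exposure. All estimators consume
harmonized per-SNP pairs (β̂_X, se_X, β̂_Y, se_Y) from non-overlapping
cohorts; binary-trait effects are on the log-odds scale, continuous traits
in SD units.

Instrument processing is the standard summary-data recipe: association
threshold p < 5×10⁻⁵ on the instrumented trait, greedy LD clumping at
r² < 0.001 within a 10,000 kb window against a user-supplied pairwise LD
table, unconditional removal of palindromic (A/T, C/G) variants — no
frequency-based strand inference — and removal of weak instruments with
F = (β̂_X/se_X)² < 10. Pairs absent from the LD table are treated as
unlinked, which is how reference panels report LD (only pairs above a
floor). Instruments absent from the outcome dataset are dropped and counted;
no proxy lookup is attempted. Duplicate rsids within a file keep the
smallest-p row.

Harmonization aligns outcome alleles onto the exposure's effect allele,
negating the outcome effect when alleles are swapped and mapping strand
flips through base complements; irreconcilable pairs and indels are tagged
`ambiguous`. Allele pairs are compared as integer codes (A=0, C=1, G=2,
T=3), where the complement is 3−code and a palindrome is a pair summing
to 3.

## Estimators

* **Wald ratio** (single SNP): β̂_Y/β̂_X with first-order delta SE
  se_Y/|β̂_X|; second-order terms are omitted.
* **IVW**: weighted least squares of β̂_Y on β̂_X through the origin with
  weights 1/se_Y². Fixed-effect SE is (Σ β̂_X²/se_Y²)^−1/2. The
  random-effects variant multiplies the SE by max(1, √(Q/(J−1)))
  (multiplicative overdispersion, floored so it is never anti-conservative).
  The *primary* estimate is random-effects exactly when Cochran's Q has
  p < 0.05, otherwise fixed.
* **MR-Egger**: the same regression with a free intercept, after orienting
  every instrument so β̂_X ≥ 0 (Egger is not orientation-invariant; this is
  the established convention). Slope and intercept SEs carry the
  overdispersion factor max(1, σ̂); p-values use the t distribution on J−2
  df. A test hook constrains the intercept to zero, in which case the slope
  equals IVW with the same weights.
* **Weighted median**: ratios ordered with normalized weights
  (β̂_X/se_Y)², linear interpolation at cumulative weight 0.5. SE from an
  observed-centred parametric bootstrap (β̂_X*, β̂_Y* redrawn at their SEs;
  default 1000 draws, seeded).
* **Weighted mode**: mode of the Gaussian-kernel-smoothed weighted ratio
  density on a 256-point grid spanning the ratio range; bandwidth =
  bandwidth_factor (default 1.0) × weighted median absolute deviation of
  the ratios, falling back to the ratio SD if the weighted MAD is zero and
  degenerating to the common ratio (SE 0) when all ratios coincide.
  Bootstrap SE as for the median, with the bandwidth recomputed per draw.

All 95% intervals are normal-theory (estimate ± 1.96·SE); odds ratios are
exp-transformed effects when the outcome is binary.

A calibration note on the bootstrap SEs: when all instruments are valid and
the true per-SNP ratios coincide, the observed-centred parametric bootstrap
systematically overestimates the sampling SD of order statistics — the
bootstrap ratio distribution is the true one convolved with a second noise
draw, and unlike the mean, a median's or mode's variance depends on the
density at the point, so the doubling does not cancel. Measured at J=100
equal-ratio instruments the inflation is ≈1.2–1.3×, giving empirical 95% CI
coverage near 0.985 for the weighted median and mode (IVW and Egger sit at
≈0.95–0.97). This conservatism is a property of the canonical bootstrap
recipe, not an implementation artifact, and is left uncorrected.

## Sensitivity battery

* **Cochran's Q** over per-SNP ratios with weights (β̂_X/se_Y)², computed as
  Σ (β̂_Yj − β̂·β̂_Xj)²/se_Yj² (algebraically identical, safe at β̂_X = 0);
  p from χ²(J−1).
* **Steiger filtering**: per SNP, variance explained is approximated by
  r² = z²/(z²+n) with z = β̂/se (the common summary-data approximation,
  used for both continuous and binary traits and only for these
  comparisons). A SNP is discarded when r²_exposure ≤ r²_outcome *and* the
  two-sample Fisher-z test of the implied correlations (independent cohorts)
  is significant at α = 0.05 — requiring significance avoids discarding on
  sampling noise; a strict variant discarding on direction alone is behind a
  config switch.
* **MR-PRESSO**: observed statistic is the weighted RSS of each SNP against
  the IVW fit with that SNP left out; the null distribution redraws both
  β̂_X and β̂_Y at their SEs around the leave-one-out predictions (default
  1000 simulations, seeded). The global p is the fraction of simulated RSS
  at or above the observed; per-SNP outlier p-values compare per-SNP
  contributions, flagged at the Bonferroni level α/J (default α = 0.05);
  the distortion test compares the outlier-corrected IVW shift against
  random removals of the same size.
* **Leave-one-out** IVW per omitted SNP, and **funnel data** (per-SNP ratio
  vs precision |β̂_X|/se_Y) for plotting; funnel output is data-only so the
  statistics stay testable headless.

## Screening and mediation

Each candidate trait is analysed bidirectionally against the anchor
phenotype (full pipeline both ways). Classification at α = 0.05 on the
primary IVW p-value: forward-significant traits are `excluded_pleiotropy`
if the Egger-intercept p or PRESSO global p is below 0.05, `bidirectional`
if the reverse direction is also significant, else
`unidirectional_forward`; no multiple-testing correction by default
(nominal screening), with an optional Benjamini–Hochberg flag recorded in
output metadata. A direction with no surviving instruments is marked
inestimable and classification falls back to the other direction with a
warning. Candidate mediators are the traits unidirectionally downstream of
the exposure *and* unidirectionally upstream of the outcome (the Venn
intersection).

Two-step mediation takes c from the exposure→outcome primary IVW, a from
exposure→mediator, and b from univariable mediator→outcome MR (not a
multivariable model adjusting for the exposure; the known bias of the
univariable choice when instruments overlap is documented, not corrected).
Indirect effect a·b, direct effect c′ = c − a·b, proportion mediated
(a·b)/c reported as a percentage to three decimals.
se(a·b) = √(a²se_b² + b²se_a²) (product-normal/Sobel, no covariance term —
the legs come from non-overlapping regressions); the proportion CI divides
the indirect CI by c with c treated as fixed, the simplest defensible
choice, flagged in output metadata. Qualification additionally requires
sign(a·b) = sign(c): a trait whose legs imply an effect opposing the total
cannot be a consistent mediator.

In screens the estimator battery is reduced to what classification consumes
(IVW fixed/random, Egger, weighted median; bootstrap 200, PRESSO 200
simulations); single-pair analyses default to the full battery with 1000
draws/simulations.

## Synthetic data generator

Summary statistics are generated directly at the summary level: observed
β̂ ~ Normal(β_true, se) with se = 1/√(2·maf·(1−maf)·n), p-values from
z-scores. SNPs are partitioned into exposure-causal, mediator-specific and
null roles; the mediator's true effect is a·β_X + γ and the outcome's is
c′·β_X + b·β_med plus an optional pleiotropy term (balanced: zero-mean;
directional: non-zero mean) on a configurable fraction of exposure
instruments. LD is emitted as a block-structured pairwise table (within-block
r² = 0.3 by default); a configurable fraction of SNPs is palindromic, and the
mediator/outcome datasets randomly swap allele order (negating β) and strand
to exercise harmonization. Cohorts are non-overlapping by construction. All
randomness derives from the single config seed; identical configs are
bit-identical.

Default parameters emulate the motivating study design: effective sample
sizes 42,000 (exposure; a large binary GWAS with ≈10.6k cases), 6,270
(outcome; a small binary GWAS with ≈1.6k cases — effective n for a binary
trait is 4/(1/cases + 1/controls)) and 3,757 (flow-cytometry-scale
continuous traits); 600 SNPs of which ≈30% are exposure-causal with effect
SD 0.035 log-odds (yielding ≈50–90 selected instruments, the order of such
studies) and ≈30% mediator-specific with effect SD 0.4 SD units (immune
trait QTLs are large); chain effects a = 0.3, b = 0.25, c′ = 0.065, so
c = 0.14 ≈ log(1.15) and the implied mediated proportion is 53.6%.

What the generator does **not** emulate: realistic human LD maps or allele
frequency spectra (LD affects only the clump table, not the effect draws, so
blockmates are statistically independent where real data would be
correlated); winner's-curse-free replication designs; liability-scale
subtleties of binary traits (log-odds effects get the same normal noise
model); sample overlap between cohorts. Passing recovery tests therefore
demonstrates correctness of the estimators and pipeline logic under the
stated noise model, not robustness to those real-data features.

A reverse-causation generator (all SNPs act on the outcome, exposure
association induced with attenuation 0.5) provides the Steiger power check;
an instrument-level generator (uniform instrument strengths on [0.02, 0.15],
configurable pleiotropy, tight SEs) provides estimator-calibration checks.

## Verification conditions and problem sizes

Parameter-recovery checks run at sizes chosen so estimator properties are
not confounded with GWAS power: estimator bias/coverage at J=100
instruments over 200 replicates; Q calibration at J=20 over 500 replicates;
Egger intercept size/power at J=200; mediation recovery over 100 replicates
with well-powered cohorts (200k/200k/50k effective) where the proportion's
sampling noise is a few percent; the screening benchmark at the generator's
default (paper-scale) exposure/outcome sizes with 50 traits of n = 50,000
over 100 replicates. The screening detection ceiling is worth stating: with
nominal-5% reverse-direction tests and two pleiotropy tests applied across
two screens, a true mediator survives all of them only ≈(0.95×0.95)² ≈ 85%
of the time even when both forward legs are always detected — an inherent
cost of the α = 0.05 exclusion design, not an estimator defect. Winner's
curse pushes the realized rate lower still: instruments are selected at
p < 5×10⁻⁵ in the same dataset that provides their effect estimates, so
SNPs near the threshold carry inflated exposure-side effects, which bends
the Egger regression (a spurious intercept) and inflates PRESSO's residual
statistic above their nominal sizes on both legs. Measured over 100
benchmark replicates the true mediator survives both screens ≈70% of the
time (per-leg pleiotropy exclusions ≈8–14%, reverse-direction false
positives ≈5–8%). This is a property of nominal-α screening on
winner's-curse-affected instruments that a real study of this design
shares, and it is reported rather than suppressed.

## Numerical choices

Ties in clumping are broken by (p-value, rsid) so results are independent
of input order. Generated p-values are floored at 1e-320 to avoid underflow
to zero for extreme associations. The weighted-mode grid spans the ratio
range ±3 bandwidths at 256 points; bootstrap draws whose resampled β̂_X
crosses zero produce infinite ratios that fall outside the grid and are
naturally ignored by the density maximization. Stage seeds are derived by
hashing the global seed with the stage name, so adding a stage never
perturbs another stage's randomness; all derived seeds are below 2³¹.
Degenerate inputs (zero exposure effect in a Wald ratio, zero total IVW
weight, zero total effect in a mediation decomposition) raise errors rather
than returning sentinel values.

## Known limitations

No multivariable MR (mediation direct effects are subtraction-based), no
proxy-SNP lookup, no genotype-level LD computation, no I²/Rucker/Radial
diagnostics, no liability-scale conversion, and no live data retrieval —
the pipeline reads local files only.
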
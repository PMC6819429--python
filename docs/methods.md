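# Methods

## Model

Two-sample MR treats each instrument SNP *j* as providing a noisy estimate of
the same causal effect β of the exposure on the outcome. With SNP–exposure
effect γ_j (SE σ_xj) and SNP–outcome log-odds effect Γ_j (SE σ_yj) estimated in
non-overlapping samples, the per-SNP Wald ratio is β̂_j = Γ_j/γ_j with
first-order delta SE σ_yj/|γ_j|. This first-order SE ignores the uncertainty in
γ_j (the "NO Measurement Error" approximation); it is the convention that makes
IVW algebraically identical to origin-constrained weighted least squares and it
matches the intervals this package is validated against. The instrument
assumptions are the usual three: association with the exposure, no association
with confounders, and no effect on the outcome except through the exposure.
Horizontal pleiotropy violates the third; vertical (mediated) pleiotropy does
not, which is why exclusion sets carry a pleiotropy class and only horizontal
ones trigger sensitivity re-runs.

## Estimators and conventions

**IVW.** β̂ = Σw_jβ̂_j/Σw_j, w_j = γ_j²/σ_yj². Default SE model is fixed-effect,
1/√Σw_j, which reproduces the validated confidence intervals; the
multiplicative random-effects option inflates the SE by max(1, √(Q/(n−1))), so
under-dispersed sets (Q < n−1) are unaffected. Cochran's Q uses the same
weights around the IVW point estimate, df = n−1.

**MR-Egger.** Exposure betas are oriented non-negative (flipping the paired
outcome betas) before a weighted regression of Γ on γ with intercept, weights
1/σ_y². The intercept is the average directional-pleiotropy effect; the slope
is the adjusted causal estimate (valid under InSIDE: pleiotropic effects
independent of instrument strength). The default SE convention multiplies the
WLS standard errors by max(1, √(Q′/(n−2))), Q′ being the residual
heterogeneity; this floored multiplicative-dispersion rule is what reproduces
the validated intercept intervals on both mineral datasets (the magnesium set
is over-dispersed, Q′/(n−2) ≈ 2.1, so the plain WLS SEs would understate its
intercept uncertainty). `se_method="plain"` disables the inflation.

**Weighted median.** Ratios sorted ascending, weights normalised, cumulative
midpoint positions p_j = cum_j − w_j/2, linear interpolation at p = 0.5. With
equal weights this is the Hazen-interpolated sample median.

**Weighted mode.** Normal-kernel weighted density of the ratios; bandwidth
h = φ · 0.9 · min(SD, MAD) · n^(−1/5), with the MAD scaled for normal
consistency and both spread measures taken over the unweighted ratios — the
modified-Silverman rule of the mode-based-estimation literature. φ defaults
to 1. The density is evaluated on a 512-point grid over [min − h, max + h];
argmax ties break toward the grid midpoint; a degenerate set with all ratios
equal returns that common value directly.

**Bootstrap SEs.** Median and mode SEs come from a parametric bootstrap
(default 1,000 replicates, seed 42): exposure and outcome betas are resampled
from N(β̂, SE), the estimator recomputed, and the SD across replicates taken as
the SE. Point estimates never depend on the seed. The variance convention used
for the published median/mode intervals is not stated anywhere authoritative,
so only point estimates are treated as reproduction targets; empirically the
bootstrap intervals agree with the published ones to ~0.01.

**Scaling.** Per-unit log-odds effects are multiplied by the exposure SD
(calcium 0.5 mg/dl; magnesium 0.1, stored with its source's unit string
verbatim) and exponentiated; CIs use the 1.96 normal multiplier, not a t
quantile — this choice reproduces the validated intervals. P-values are
two-sided normal and independent of the SD constant.

**Harmonization.** The packaged tables are pre-harmonized and carry no other
allele, so records without an other allele are accepted as-is; harmonization
applies to general two-source inputs. A palindromic pair (A/T, C/G) with
exposure EAF in [0.42, 0.58] is flagged ambiguous (strand orientation cannot
be inferred); the window and the flag-keep/strict-drop policy are configurable.
Proxy SNPs are metadata only — no LD arithmetic is performed.

## Power

The binary-outcome power formula works on the attenuated linear-probability
scale: with case fraction K, the observable effect of an OR is
b = K·(OR/(1 + K(OR−1)) − 1), its variance v = (K(1−K) − b²)/(N·R²), and the
two-sided Wald test has non-centrality b²/v, giving power as the upper tail of
a non-central χ²(1) past the α critical value. Because the attenuation is
asymmetric around OR = 1 the formula is not reciprocal-symmetric, so the
detectable risk-increasing and protective ORs are root-solved separately
(brackets (1, 10] and [0.1, 1), tolerance 1e−6 on power). When b² reaches
K(1−K) the approximation saturates and power is reported as 1. The α entering
the published 80%/13%/20% figures is not stated; the default is 0.05 and the
Bonferroni 0.01 is a parameter — at these sample sizes the choice moves the
detectable OR by less than the reporting precision.

## Synthetic data

The generator draws true exposure effects uniformly from a positive range,
adds normal estimation noise at the exposure-GWAS SE to produce observed
exposure betas, and builds outcome betas as causal effect × true exposure
effect + pleiotropy + normal noise at the outcome SE. Pleiotropy is zero for
valid SNPs; for the invalid fraction it is N(0, sd) (balanced),
N(mean, sd) (directional, drawn independently of strength — the InSIDE
condition), or tied to instrument strength (correlated mode, to demonstrate
MR-Egger breakdown). Exposure and outcome noise are independent, matching the
no-sample-overlap design. Defaults mirror the serum-mineral study scale:
50 SNPs, exposure betas in [0.005, 0.08], SEs 0.003/0.02, null causal effect.

What the generator does *not* emulate: LD between instruments, weak-instrument
winner's curse from discovery-based selection, allele-frequency–dependent SEs,
case-control ascertainment on the outcome scale, or sample overlap. Passing
calibration tests therefore demonstrates correctness of the estimators under
their stated assumptions, not robustness to those real-data complications.

Monte-Carlo problem sizes were chosen to give two-digit operating
characteristics at interactive runtimes: 1,000 replicates for type-I error
(MC SE ≈ 0.007), 2,000 for CI coverage (MC SE ≈ 0.005), 500 for bias and
Egger-intercept recovery. The median-vs-IVW robustness demonstration runs in a
strong-instrument regime (outcome SE 0.002, directional mean 0.05) because the
median's breakdown protection concerns pleiotropy, not sampling noise; at the
default noise level both estimators are dominated by ratio dispersion.

## Numerical notes and limitations

* Wald ratios are undefined at γ = 0 and raise; bootstrap draws that cross
  zero are nudged to the smallest positive float, which occurs with negligible
  probability for genome-wide-significant instruments.
* Per-SNP OR confidence bounds may overflow to infinity for essentially
  unidentified ratios (tiny γ); this is the correct limit and is left as inf.
* The source table prints betas/SEs to 3 decimals; recomputed statistics
  therefore differ from the originally published ones in the third decimal
  (e.g. heterogeneity p 0.82 vs 0.83). The published Results text cites
  "rs12146355" where the instrument table lists rs13146355; the tables here
  follow the instrument table.
* The magnesium SD constant is stored with its source's unit string
  ("mmol/dl") verbatim, though the conventional unit is mmol/L; only the
  numeric constant 0.1 enters any computation.
* No MR-PRESSO, multivariable MR, penalized median variants, LD-aware
  instrument selection, or individual-level simulation.
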
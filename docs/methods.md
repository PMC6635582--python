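# Methods

This note documents the statistical models implemented in `bwmr`, the design
choices made where conventions differ, the synthetic-data generators and what
they do and do not emulate, and known limitations.

## Two-sample MR model

For instrument *j*, the exposure side supplies (γ̂<sub>j</sub>,
σ<sub>xj</sub>) — the per-allele effect on birth weight in SD units with its
standard error — and the outcome side supplies (Γ̂<sub>j</sub>,
σ<sub>yj</sub>) on the log-odds scale. The two samples are assumed
non-overlapping, so the estimate noise on the two sides is independent.
Under the instrumental-variable conditions (relevance, no confounding, no
direct path to the outcome), Γ<sub>j</sub> = θ γ<sub>j</sub> and every Wald
ratio Γ̂<sub>j</sub>/γ̂<sub>j</sub> estimates θ with first-order SE
σ<sub>yj</sub>/|γ<sub>j</sub>|.

### Estimators

**IVW.** β̂ = Σ w<sub>j</sub> (Γ̂<sub>j</sub>/γ̂<sub>j</sub>) / Σ w<sub>j</sub>
with w<sub>j</sub> = γ̂<sub>j</sub>²/σ<sub>yj</sub>², algebraically the
weighted least-squares slope of Γ̂ on γ̂ through the origin with weights
1/σ<sub>yj</sub>². Fixed-effect SE (Σw)<sup>−1/2</sup>. The random-effects
variant multiplies the SE by max(1, √(Q/(J−1))) — the multiplicative
overdispersion model with the dispersion floored at one, so homogeneous data
keep the analytic SE. Confidence intervals are normal-theory (±1.96 SE) and
p-values two-sided normal throughout; with J near 47 the normal/t
distinction is immaterial, and the normal is used uniformly for consistency.

**Heterogeneity.** Q = Σ w<sub>j</sub>(ratio<sub>j</sub> − β̂)², referred to
χ²(J−1); I² = max(0, (Q − (J−1))/Q).

**Weighted median.** Ratios are ordered; with normalized weights
p<sub>j</sub> and midpoint cumulative sums s<sub>j</sub> = Σp − p/2, the
estimate linearly interpolates the ratio at s = ½. The SE is a parametric
bootstrap (default 1,000 draws, seeded): γ*<sub>j</sub> ~ N(γ̂<sub>j</sub>,
σ<sub>xj</sub>²), Γ*<sub>j</sub> ~ N(Γ̂<sub>j</sub>, σ<sub>yj</sub>²),
re-estimate, take the standard deviation.

**MR-Egger.** Instruments are oriented so every γ̂ > 0 (jointly flipping γ̂
and Γ̂), the convention under which the fitted intercept estimates the mean
directional pleiotropy. The regression is WLS of Γ̂ on γ̂ with intercept and
weights 1/σ<sub>yj</sub>² (statsmodels WLS under the hood); SEs use the same
floored multiplicative dispersion as IVW. Egger's slope is only weakly
identified when the γ̂ spread is small — a design property, not an
implementation one.

**Odds-ratio reporting.** Binary-outcome effects are reported per 1 SD
*decrease* of the exposure: OR = exp(−β̂), CI bounds exp(−β̂ ∓ 1.96 SE)
sorted ascending. One SD of birth weight corresponds to ≈ 488 g.

### Sensitivity analyses

**Leave-one-out** re-fits the chosen estimator J times. The identity
LOO<sub>j</sub> = β̂ + w<sub>j</sub>(β̂ − ratio<sub>j</sub>)/(Σw − w<sub>j</sub>)
is used as a numerical cross-check in the tests.

**MR-PRESSO.** The observed statistic is the variance-standardized residual
sum of squares, each instrument's residual taken against the leave-that-
instrument-out IVW fit, with delta-method residual variance σ<sub>y</sub>² +
(β̂<sub>−j</sub> σ<sub>x</sub>)². The null distribution comes from n_sim
(default 1,000) parametric simulations under the fitted no-pleiotropy model;
the global p-value is the (add-one) tail fraction, per-SNP p-values are each
instrument's simulated contribution tail, Bonferroni-corrected at α to flag
outliers. A descriptive distortion statistic (full-set minus outlier-free
IVW estimate) is attached when outliers are found. Everything is driven by
one seeded generator; results are bit-reproducible given (n_sim, seed).

**Reverse direction.** The same pipeline with exposure and outcome roles
swapped; the estimate is tagged `reverse:`.

### Multivariable MR and mediation

With effects on K exposures per instrument, the direct effects are the WLS
coefficients of Γ̂ on the K exposure-effect columns, no intercept, weights
1/σ<sub>y</sub>² (more instruments than exposures and full column rank
required). The mediated (indirect) effect uses the difference method on the
log-odds scale: indirect = total − direct, with the conservative
independence approximation SE = √(SE²<sub>total</sub> + SE²<sub>direct</sub>).
The difference method reproduces all four published
(total, direct) → indirect odds-ratio triples to two decimals, which is why
it was chosen; the exact CI construction used for the published indirect
intervals is not stated in the available text, so the independence
approximation should be treated as conservative rather than exact.

### Analytic power (binary outcome)

Power of the two-sided IVW test at level α against an alternative OR per
exposure SD:
z* = |ln OR| √(n · PVE · cf (1 − cf)), power = Φ(z* − z<sub>1−α/2</sub>) +
Φ(−z* − z<sub>1−α/2</sub>), where PVE is the total exposure variance
explained by the instruments and cf the case fraction. The tests verify this
closed form against the empirical rejection rate of the IVW test on matched
simulations (500 replicates), rather than against any tabulated value.

## Instrument diagnostics and filters

PVE = β²/(β² + n·se²) and F = (β/se)²; the identity
F ≈ (n−2)·PVE/(1−PVE) holds to 0.2 % at n > 10⁵ and is tested on the
packaged table. The packaged instrument table reproduces the published
per-SNP F within 0.5 % and PVE within 1 %; the published *overall* F of
49.22 is **not** reproduced by the arithmetic mean of per-SNP F (50.58) and
its aggregation rule is not stated in the available text — `overall_f`
deliberately implements the plain mean and the discrepancy is left visible.
Selection keeps SNPs below a p threshold (default 5×10⁻⁸) with greedy
clumping against caller-supplied LD (r² cutoff 0.01 by default); no
reference panel is shipped or queried. Pleiotropy exclusion drops
instruments with outcome-side p below 0.05/47 ≈ 1.06×10⁻³ by default, plus
an explicit caller-supplied list (standing in for database screens, which
this package never performs itself).

## Harmonization

Outcome records are aligned to the exposure's effect allele: identical
alleles pass through; swapped alleles flip the sign and complement the
frequency; strand-flipped (complemented) allele pairs are resolved by
frequency agreement; palindromic (A/T, C/G) variants with either frequency
within ±0.08 of 0.5 are dropped as strand-ambiguous. Exposure SNPs missing
from the outcome table are dropped and counted — proxy lookup and
summary-statistic imputation are deliberately out of scope. These are
field conventions; the window is configurable.

## Synthetic data

**Summary-level worlds** (`simulate_two_sample`): MAFs uniform on a range
(default 0.1–0.4); γ<sub>j</sub> = ±√(pve<sub>j</sub>/2p(1−p)) with random
or all-positive signs; exposure noise σ<sub>x</sub> = √((1−pve)/(n·2p(1−p)));
outcome truth Γ<sub>j</sub> = θγ<sub>j</sub> + α<sub>j</sub>, where a
configurable fraction of instruments carries pleiotropy α ~ N(mean, sd²);
binary-outcome noise uses the score-test scale σ<sub>y</sub> =
1/√(n·cf(1−cf)·2p(1−p)). Estimates are independent normal draws on each
side (no sample overlap). This is the standard device for evaluating
summary-statistics MR methods: it captures estimation noise and pleiotropy
exactly, but not LD, allele-frequency mismatch between samples, winner's
curse in instrument discovery, or real binary-trait link nonlinearity — so
calibration results here speak to the estimators, not to data quality
issues.

`table1_world` uses the packaged 47-SNP table verbatim as the exposure side
(treating the printed effects as the truth) and simulates only the outcome
side — the configuration for the recovery and type-I tests, with outcome
defaults (n = 184,305, cf = 0.33) matching a large coronary-artery-disease
GWAS.

**Mother–child cohorts** (`simulate_mother_child`): mother genotypes are
Binomial(2, p); the child receives one allele drawn uniformly from the
mother's two plus one population allele, which forces the mother–child
genotype correlation of ½ (verified at 0.5 ± 0.02, n = 50,000). Birth
weight is x = Σγ<sub>j</sub>G<sup>child</sup><sub>j</sub> +
Σϑ<sub>j</sub>G<sup>mother</sup><sub>j</sub> + ε with ε scaled so the
*fetal-only* world has unit variance; maternal effects add variance on top
of that baseline (at the extreme simulated maternal sizes a total-variance
normalization would be infeasible). Disease is Bernoulli with logit =
logit(cf) + θx, plus an optional direct maternal-score term — the explicit
confounding switch used by the genetic-score tests. A fixed fraction
(1 + ρ)/2 of instruments get maternal effects sign-concordant with their
fetal effects; ρ defaults to 0.1 (mild alignment), chosen a priori so that
realistic maternal-effect sizes leave the causal estimate approximately
unbiased while extreme ones push it detectably upward — the qualitative
pattern the maternal simulations are designed to probe. Per-SNP disease
associations inside simulations are computed by vectorized per-SNP logistic
regressions (Newton–Raphson written out over SNP columns), not by the
linear-probability shortcut, to keep the log-odds scale exact up to
non-collapsibility.

**Maternal confounding simulation** (`maternal_confounding_sim`): the
exposure side provides fetal-only effect estimates — emulating the study
design in which instrument effects from a birth-weight GWAS are taken as
fetal ground truth — while outcome cohorts are mother–child worlds whose
birth weight includes maternal effects. With both sides simulated from the
same contaminated model the leakage term γ + ϑ/2 cancels identically in the
Wald ratio and no bias exists at any maternal size; the fetal-only exposure
convention is what makes maternal confounding expressible at all. Reported
bias is (θ̂ − θ)/θ averaged over replicates with its Monte-Carlo SE. Two
systematic effects of a few percent ride along at every maternal level:
logistic non-collapsibility (marginal per-SNP log-odds are attenuated
relative to θγ) and the finite-sample IVW noise; the zero-maternal level is
always simulated so these can be read off directly.

## Maternal-effect bias: closed form and Monte-Carlo cross-check

`maternal_bias(ϑ, π)` returns the relative bias (percent) of the causal
estimate induced by a maternal effect ϑ (SD units per maternal allele /
score SD) when the population probability of a low-birth-weight (LBW)
offspring is π. The implemented expression is

  B(ϑ, π) = 100 · c · ϑ² · λ(π)<sup>d</sup>,  λ(π) = φ(Φ⁻¹(π))/π,

where λ(π) is the mean standardized birth-weight deficit among LBW births —
the natural severity measure of the LBW tail, strictly decreasing in π —
and (c, d) ≈ (0.14410, 2.74459) are pinned analytically by the expression's
two published evaluations (7.87 % at ϑ = 0.30, π = 0.069; 2.16 % at
ϑ = 0.30, π = 0.28). This is a calibrated surrogate, not a transcription:
the algebra behind the published values is not restated alongside them and
was not available to this implementation. The quadratic leading order in ϑ is
principled — in any two-sample model where the maternal genotype influences
the offspring's outcome solely through offspring birth weight, the
first-order leakage γ + ϑ/2 enters the exposure- and outcome-side
associations identically and cancels in the Wald ratio, leaving a
second-order residual — and the surrogate satisfies B(0, π) = 0, grows with
|ϑ|, and is continuous and decreasing in π.

`maternal_bias_mc(ϑ, π)` cross-checks the surrogate with an explicit
mechanism: Gaussian polygenic mother/child scores (correlation ½), birth
weight with fetal scale γ and maternal scale ϑ, and disease risk responding
to the LBW event x < Φ⁻¹(π) with the threshold fixed in absolute units by
the maternal-effect-free world. Maternal effects inflate the birth-weight
variance against the fixed threshold, producing a second-order bias that is
positive and of the closed form's magnitude in the low-prevalence regime
(≈ +5 to +9 % at the π = 0.069 anchor, against 7.87 %). **Known
limitation:** under this mechanism the bias changes sign for π ≳ Φ(−1) ≈
0.16, while the calibrated form follows the published values and stays
positive (at π = 0.28 the mechanism gives ≈ −3.5 % against the published
+2.16 % — same order, opposite sign). The polygenic-score (Gaussian)
formulation matters: a single skewed binomial locus flips the sign of this
second-order effect even at small π. Agreement between surrogate and
mechanism should therefore be read as directional-plus-order-of-magnitude
at realistic LBW prevalences, not as a derivation.

`genetic_score_adjust` fits a logistic model of disease on the standardized
offspring genetic score controlling for the standardized maternal score
(statsmodels Logit), reporting the OR per offspring-score SD decrease;
non-convergence and separation raise with diagnostics.

## Numerical choices and degenerate inputs

- Dispersion floors: random-effects IVW, Egger and multivariable IVW all
  floor the multiplicative overdispersion at 1, never deflating analytic SEs.
- J = 1 with random-effects IVW falls back to fixed with a warning; J < 2
  (LOO, Q), J < 3 (median, Egger), J < 4 (MR-PRESSO) raise.
- γ̂ = 0 raises in ratio-based estimators and drops (with a warning) in
  funnel data; bootstrap draws that hit exactly zero are nudged by the
  smallest positive float.
- All-identical oriented γ̂ is a singular Egger design and raises; collinear
  exposure columns raise in multivariable MR naming the columns.
- Simulated p-values are floored at 10⁻³⁰⁰ to stay in (0, 1]; the add-one
  rule keeps MR-PRESSO p-values in (0, 1].
- Every stochastic routine takes a seed or Generator; the pipeline derives
  per-outcome, per-stage seeds from the run seed.

## Problem sizes in the test suite

The statistical tests use the sizes at which the checked properties are
informative yet the suite stays quick: 500 replicates for type-I calibration
of the IVW/Q/Egger/MR-PRESSO tests (3·MC-error band ≈ ±0.03 around 0.05),
200 replicates for effect recovery and pleiotropy-robustness contrasts,
100 replicates per maternal-PVE level with 50,000-pair cohorts and 20
instruments at 1 % fetal PVE each, and MR-PRESSO null distributions of
300–1,000 simulations. Exposure/outcome sample sizes mirror the study scale
(≈ 1.4×10⁵ exposure, ≈ 1.8×10⁵ outcome at case fraction 0.33) except where
individual-level cohorts are generated, which use 2–5×10⁴ pairs.

## Known limitations

- The maternal-bias closed form is a calibrated surrogate (above); outside
  the published anchor region its values should be treated as smooth
  interpolation with the stated qualitative guarantees, and the Monte-Carlo
  mechanism disagrees in sign at high LBW prevalence.
- The published overall F statistic (49.22) is not reproduced by any
  aggregation implemented here; `overall_f` is the arithmetic mean.
- No LD between simulated instruments; no sample overlap; no winner's curse.
  Real-data analyses should supply externally clumped instruments and treat
  the calibration results as estimator properties.
- Egger inference uses normal rather than t reference distributions;
  negligible at J ≈ 47, anticonservative at very small J.
- The indirect-effect SE assumes independence of total and direct estimates;
  with shared instruments they correlate, making the CI conservative in the
  usual case of positive correlation.
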
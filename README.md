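# bwmr — two-sample Mendelian randomization for birth weight and adult disease

`bwmr` implements a complete two-sample Mendelian randomization (MR) pipeline
for testing whether birth weight causally affects adult disease risk — the
*fetal origins of adult diseases* question. It is aimed at statistical
geneticists and epidemiologists who work from GWAS summary statistics: no
individual-level data are required for the main analysis, and a packaged
47-SNP birth-weight instrument table plus a synthetic-data generator make
every stage testable offline.

## The model

Each SNP *j* serves as an instrumental variable with effect γ<sub>j</sub> on
birth weight (SD units; 1 SD ≈ 488 g) and Γ<sub>j</sub> on the disease
(log-odds). Under valid instruments Γ<sub>j</sub> = θ·γ<sub>j</sub>, and
each Wald ratio Γ<sub>j</sub>/γ<sub>j</sub> estimates the causal effect θ.
The estimator ensemble:

- **IVW** — inverse-variance-weighted mean of the Wald ratios with weights
  w<sub>j</sub> = γ<sub>j</sub>²/σ<sub>yj</sub>² (equivalently, weighted
  regression of Γ on γ through the origin). The random-effects version
  inflates the SE by max(1, √(Q/(J−1))) to absorb effect heterogeneity,
  measured by Cochran's Q and I².
- **Weighted median** — the ratio value at cumulative weight ½; consistent
  when instruments carrying ≥50 % of the weight are valid. SE by parametric
  bootstrap.
- **MR-Egger** — weighted regression of Γ on γ *with* an intercept
  (instruments oriented so γ > 0); a nonzero intercept estimates directional
  horizontal pleiotropy.
- Diagnostics: per-SNP PVE = β²/(β² + n·se²) and F = (β/se)², leave-one-out,
  MR-PRESSO global/outlier simulation tests, funnel data, reverse-direction
  MR, analytic power for binary outcomes, multivariable MR with the
  total = direct + indirect mediation decomposition (log-odds scale), and
  maternal-effect confounding analytics (closed-form bias plus mother–child
  cohort simulations with genotype correlation ½).

Binary-outcome results are reported as odds ratios per **1 SD decrease** of
birth weight, OR = exp(−θ̂), the convention for low-birth-weight risk.

## Worked example

Simulate a disease GWAS (184,305 samples, 33 % cases) with a true odds ratio
of 1.34 per SD decrease of birth weight, using the packaged 47-SNP
instrument table as the exposure side, and run the ensemble:

```python
import math
from bwmr import (
    load_table1_fixture, overall_f, table1_world, paired_instruments,
    ivw, weighted_median, egger, to_or_per_sd_decrease,
    mr_power_binary, PowerQuery, maternal_bias,
)

instruments = load_table1_fixture()
print(f"instruments: {len(instruments)}  mean F: {overall_f(instruments):.2f}")

exposure, outcome = table1_world(theta=-math.log(1.34), n_outcome=184_305,
                                 case_fraction=0.33, seed=7)
harmonized = paired_instruments(exposure, outcome)
est = ivw(harmonized, mode="random")
orr = to_or_per_sd_decrease(est)
print(f"IVW (random effects): OR per SD decrease = {orr.or_per_sd_decrease:.2f} "
      f"(95% CI {orr.ci_low:.2f}-{orr.ci_high:.2f}), p = {est.pval:.2e}")
print(f"heterogeneity: Q = {est.q_stat:.1f}, I^2 = {100 * est.i2:.1f}%")

wm = weighted_median(harmonized, n_boot=1000, seed=7)
eg = egger(harmonized)
print(f"weighted median OR: {to_or_per_sd_decrease(wm).or_per_sd_decrease:.2f}; "
      f"Egger slope OR: {to_or_per_sd_decrease(eg.slope).or_per_sd_decrease:.2f}, "
      f"intercept p = {eg.intercept_pval:.2f}")

power = mr_power_binary(PowerQuery(n_outcome=184_305, pve=0.015,
                                   case_fraction=0.33, or_alt=1.34, alpha=0.05))
print(f"analytic power at OR 1.34: {power:.3f}")
print(f"maternal bias at (0.30, 6.9%): {maternal_bias(0.30, 0.069):.2f}%")
```

Output:

```
instruments: 47  mean F: 50.58
IVW (random effects): OR per SD decrease = 1.33 (95% CI 1.23-1.43), p = 6.62e-14
heterogeneity: Q = 38.9, I^2 = 0.0%
weighted median OR: 1.33; Egger slope OR: 1.34, intercept p = 0.91
analytic power at OR 1.34: 1.000
maternal bias at (0.30, 6.9%): 7.87%
```

The IVW estimate recovers the simulated OR of 1.34 within sampling error;
all 47 instruments are strong (F between 29.4 and 179.8, well above the
conventional bar of 10); the near-zero Egger intercept (p = 0.91) shows no
directional pleiotropy in this clean simulation; and a maternal effect as
large as 0.30 SD would distort the estimate by only ~8 % even at a 6.9 %
low-birth-weight prevalence.

The same pipeline is available from the shell:

```bash
bwmr simulate --theta -0.2927 --n-snps 47 --seed 7 --out sim/
bwmr analyze --exposure sim/exposure.tsv --outcome cad=sim/outcome.tsv:binary \
             --seed 1 --out run/
bwmr power --n-outcome 184305 --or 1.34 --pve 0.015 --case-fraction 0.33
bwmr maternal-bias --vartheta 0.30 --pi 0.069
```

## Layout

| module | contents |
|---|---|
| `bwmr.summary_io` | summary-statistics I/O, validation, allele harmonization, packaged instrument table |
| `bwmr.instruments` | PVE / F diagnostics, p-value selection with LD clumping, pleiotropy exclusion |
| `bwmr.estimators` | Wald ratio, fixed/random IVW, Q/I², weighted median, MR-Egger, OR reporting |
| `bwmr.sensitivity` | leave-one-out, MR-PRESSO, funnel data, reverse-direction MR |
| `bwmr.multivariable` | multivariable IVW, total/direct/indirect decomposition |
| `bwmr.power` | analytic power for binary outcomes |
| `bwmr.maternal` | maternal-effect bias (closed form + Monte Carlo), genetic-score adjustment, confounding simulations |
| `bwmr.synthetic` | summary-level and mother–child cohort generators |
| `bwmr.pipeline`, `bwmr.cli` | multi-outcome orchestration with Bonferroni correction; `bwmr` console script |

See `docs/methods.md` for the statistical methods, generator design, and
known limitations.
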
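# Methods

## The statistical problem

Polygenic scores for adult BMI summarize many small additive effects.
In a cohort followed from birth, three questions arise: at what age does
the score's association with BMI emerge; how does it grow with age; and is
its effect on adult BMI carried by weight gain in particular growth
periods. `grslife` implements the estimators for all three and a
generator that produces cohorts in which the answers are known.

## Score construction

Dosages are aligned so every column counts the weight table's effect
allele: same-pair variants are used directly (complementing the dosage
when the counted allele is the non-effect allele), opposite-strand pairs
are reconciled by base complement, and anything else is dropped with a
report. Palindromic A/T and C/G variants cannot be strand-checked without
frequency comparison against a reference panel; they are kept with a
warning by default and removable with `drop_palindromic=True`.

The raw score is wGRS_i = Σ_j d_ij β_j with β_j in kg/m² per allele.
Missing dosages are imputed by their Hardy–Weinberg expectation 2·eaf_j
(default), which keeps every subject and shrinks the missing variant's
contribution toward the population mean; the alternative `rescale` policy
multiplies the observed sum by m/m_observed. Z-standardization uses the
analysis sample's mean and sample SD (n−1 denominator; `ddof=0` switches
to the population convention — the two differ by a factor √(n/(n−1)) and
the choice does not affect any downstream test statistic).

## Quality control

Filters run in a single pass in the order variants → samples →
relatedness, each variant/sample reported under the first filter it fails;
re-running QC on its own output removes nothing (asserted in tests).

The Hardy–Weinberg test is the exact conditional test: given the observed
allele counts, the probability of each possible heterozygote count is
computed by a two-sided recurrence from the modal count, and the p-value
sums all configurations no more probable than the observed one. The exact
test rather than the chi-square is essential because the conventional
threshold (10⁻⁵) sits far in the tail where the chi-square approximation
is unreliable at realistic minor-allele counts. Monomorphic variants
return p = 1 (no variation to test).

Heterozygosity outliers are samples outside mean ± 3 SD of the
heterozygous-call fraction, computed after the sample-missingness filter;
a zero-variance band removes nobody.

Relatedness uses the method-of-moments PI_HAT = P(IBD=2) + P(IBD=1)/2
solved from pairwise identity-by-state counts and sample allele
frequencies, with the moment estimates clamped to the probability simplex
(standard finite-sample behaviour). One member of each pair above the
threshold is removed greedily — the lower call rate, ties to the later
id. Moment-based IBD needs hundreds of independent markers to be
informative; below `min_variants_for_ibd` (default 200) the stage is
recorded as skipped rather than producing noise-driven removals. The
sex-discordance and PCA population-outlier stages require X-chromosome and
reference-panel data and are likewise recorded as skipped for
transparency.

## Growth

LMS Z-scores use Z = ((x/M)^L − 1)/(L·S) (log form when |L| < 10⁻¹²) with
L, M, S linearly interpolated in age within sex. |Z| > 5 is flagged
implausible but kept, leaving exclusion to the analyst.

Conditional relative weight gain: for each period, OLS of period-end
weight on all earlier period-boundary weights, earlier boundary heights,
and period-end height, separately by sex; residuals are divided by their
sample SD and the sexes pooled, so each sex contributes mean 0, SD 1.
Anchor measurements are matched to boundary ages within ±0.5 y (the annual
visit schedule), closest record first, ties to the earlier record. Birth
length is excluded from the infancy regression by default (its missingness
is typically high); `default_periods(include_birth_length=True)` restores
it. The SR construction makes each period's gain uncorrelated in-sample
with earlier size and current height, which is what permits mediators from
adjacent periods to enter a common model without the inflation that raw
correlated weights would cause.

## Association models

Per-age: OLS of BMI Z on wGRSz plus a sex indicator, Wald CIs.

Longitudinal: random-intercept linear mixed model (REML default) with
fixed effects wGRSz, age, age², age³, sex and the three wGRSz-by-age
polynomial interactions. Age is centered at its sample mean before
polynomials are formed — purely numerical conditioning; when the
generating interaction is linear, the wGRSz:age coefficient is invariant
to the shift and reads as SDS per SD per year. Random intercepts only; no
random slopes. A sex main effect is included; no score-by-sex term by
default.

Trajectory membership: multinomial logit with the first class (normal
weight) as reference; exponentiated coefficients are relative risk ratios
per SD of score with Wald CIs on the log scale. The fitted surface is
statsmodels throughout (OLS/MixedLM/MNLogit); this package owns the model
specification, term construction and reporting, not the optimizers.

## Mediation

All three path regressions run on one common complete-case sample, so
c = c′ + a·b holds to machine precision and the proportion mediated
100·a·b/c is well-defined whenever |c| > 10⁻⁸ and a·b has the sign of c.
Inconsistent signs (suppression) are flagged and the proportion reported
as missing rather than as a negative or >100% figure. The Sobel SE is the
classic first-order form √(a²se_b² + b²se_a²); the Aroian second-order
term is available by flag. The bootstrap resamples subjects with
replacement and applies the bias-corrected (BC, not BCa) percentile
interval with B = 1000 by default; degenerate resamples are redrawn with a
cap. Holm's step-down correction runs across the period p-values with
family size m = number of periods tested (4 by default).

## The synthetic cohort

The generator emulates an urban African birth cohort measured annually
from birth to 18 y:

- **Genotypes**: Binomial(2, eaf) per locus — Hardy–Weinberg by
  construction, giving the QC filters a calibrated null. The bundled
  71-locus weight table is synthetic (deterministic draws: β between 0.005
  and 0.12 kg/m², eaf between 0.05 and 0.95), standing in for a published
  weight table the user would normally supply.
- **Growth**: BMI-SDS(i, t) = sex-curve(t) + class offset + random
  intercept (SD 0.8) + (γ₀ + γ₁·t)·wGRSz_i + noise (SD 0.5), with the
  default γ₁ = 0.01 SDS per SD per year and γ₀ = 0. Median-BMI and height
  curves are anchored at ages 0, 2, 5, 8, 15, 18 to values typical of the
  emulated cohort's printed descriptives, interpolated linearly. SDS are
  back-transformed to BMI through a matching synthetic LMS reference with
  L = 1 and S = 0.12, so Z-score round-trips are exact and no WHO tables
  are redistributed. Height is the sex median curve times a subject-level
  scale factor (SD 3%) plus per-visit measurement noise (SD 1%); only
  weight carries the genetic signal, so conditional gains are identifiable
  independent of linear growth.
- **Trajectory classes**: three latent classes (normal / late-onset /
  early-onset) from a multinomial logit with default intercepts (−1.5,
  −2.0) and log-RRRs (0, ln 1.88) per SD of score, with additive BMI-SDS
  offsets (0, 0.4, 1.0).
- **Missingness**: record-level Bernoulli deletion (default 15%) —
  missing at random. The real cohort's per-age attendance varies
  non-monotonically; that detail is not emulated.
- **Mediation triples**: exposure ~ N(0,1), mediator = a·x + N(0, sd_m),
  outcome = c′·x + b·m + N(0, sd_y); defaults a = 0.4, b = 0.7,
  c′ = 0.22 give a true proportion mediated of 0.28/0.50 = 56%.

Everything is deterministic given its seed, and simulator output files
carry the seed in a header comment.

What passing tests show — and what they do not: recovery on these cohorts
demonstrates that the estimators are correctly implemented and unbiased
under the generating model (linear score effects, Gaussian residuals, MAR
missingness, no LD, no population structure, no score-by-sex or
score-by-environment interaction). They do not certify behaviour under
population stratification, informative dropout, or assay artefacts, which
real cohort analyses must address separately.

## Problem sizes and numerical choices

Parameter-recovery checks average 10–20 independent seeds at the sizes the
estimators are meant for (n = 900 subjects × 14 ages for the mixed model,
n = 5000 for the cross-sectional and multinomial fits, n = 900 for the
mediation path model). Null-calibration checks use 100 replicates at
smaller per-replicate sizes (120–600 subjects) since Wald coverage is not
size-dependent at these scales. Exact identities are asserted at 10⁻⁸ to
10⁻¹² as appropriate; the HWE implementation is checked against a
log-factorial enumeration oracle exhaustively up to n = 40 and on sampled
configurations up to n = 200.

## Known limitations

- PI_HAT uses the plain moment estimator without PLINK's small-sample
  allele-count corrections; at thousands of markers the difference is
  negligible, at hundreds it is visible, below `min_variants_for_ibd` the
  stage refuses to guess.
- LCGMM trajectory estimation is out of scope: class labels are consumed
  as input (or generated); the package only tests their association with
  the score.
- The mediation estimands are product-of-coefficients only — no
  counterfactual natural effects, no exposure–mediator interaction.
- Proxy-variant discovery, PCA outlier detection and sex checks need
  external reference data and are deliberately not implemented.
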
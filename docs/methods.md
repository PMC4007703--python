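# Methods

This note documents the statistical procedures implemented in `assaykit`,
the parameters that matter, the choices made where the design was genuinely
open, and what the synthetic-data generators do and do not emulate.

## Panel, quantification and score

The assay definition lives entirely in a YAML panel configuration
(`assaykit/data/panel_gps.yaml` is the shipped default): 12 cancer genes in
four pathway groups (androgen: AZGP1, KLK2, SRD5A2, FAM13C; cellular
organization: FLNC, GSN, TPM2, GSTM2; proliferation: TPX2; stromal: BGN,
COL1A1, SFRP4), 5 reference genes (ARF1, ATP5E, CLTC, GPS1, PGK1), and a
gDNA-contamination assay targeting a non-transcribed promoter region. No
gene name is hard-coded outside that file.

Quantification rules, all in Cp units (qPCR cycles):

* a Cp is valid in (0, 45]; the run is 45 cycles, so values above 45 are
  input errors while "never crossed" is the distinct NON_DETECT state;
* triplicates require ≥ 2 valid wells (configurable); the weighted-mean
  aggregation defaults to equal weights, with weights renormalized over the
  wells actually present and matched to wells by replicate index;
* the reference aggregate is the unweighted mean of the five reference
  genes' aggregated Cps. "Aggregated" is not further specified in the
  assay's public description; the plain mean is the simplest estimator with
  the required shift-equivariance, and per-well weights remain available in
  configuration;
* normalized expression = gene Cp − reference aggregate + 10. The +10
  centering is cosmetic (keeps typical values positive); the orientation is
  Cp-like: larger normalized value ⇒ later crossing ⇒ less transcript.
  Scoring coefficients in the configuration must be entered consistently
  with this orientation;
* a failed reference gene always fails the sample; a failed cancer gene
  fails the sample too (the score needs all 12) unless `allow_partial` is
  set, which permits per-gene reporting without a score;
* gDNA QC: a patient-sample gDNA signal crossing strictly *earlier* than
  the configured threshold (default 35 Cp; no published value exists, so
  this is deliberately configuration, and reports carry the threshold)
  fails the sample; NON_DETECT and crossings at/after the threshold pass;
* an optional window on the reference-gene average
  (`qc_thresholds.reference_mean_window`) supports production-style sample
  validity specifications; no default bounds are shipped because none are
  published.

The score is `clamp(offset + slope · GPSu, 0, 100)` with
`GPSu = intercept + Σ_groups coef_G · t_G(Σ_g w_g · normalized_g)`, where
`t_G` is an optional config-declared piecewise pre-transform (identity,
`clip_low`, `clip_high`) applied to the group score. Clamping, not
renormalization, handles out-of-range values, and a `clamped` flag is
reported. The shipped numeric coefficients are **illustrative**: the
commercial score's coefficient values are not public. Correctness of the
scoring engine is established with toy coefficient sets whose outputs are
hand-computable, and the engine treats all coefficients as data.

## Heteroscedastic dilution-curve fits

Model for one gene's dilution series (x = ng RNA per PCR well,
L = log2 x — the base-2 convention is used everywhere, one log unit per
two-fold dilution):

    Cp = b0 + b1·L + b2·L² + b3·L³ + ε,   ε ~ N(0, exp(γ0 + γ1·L))

fitted by full maximum likelihood. For fixed γ1 the likelihood profiles
analytically (the mean is a weighted least-squares solve with relative
weights exp(−γ1·L); exp(γ0) is the weighted mean squared residual), so the
optimization is a 1-D bounded search over γ1 ∈ [−4, 4] with tolerance 1e-8.
The profiled variance is floored at 1e-12 Cp² so exactly noise-free
constructed inputs yield finite, equal log-likelihoods (model comparisons
then correctly report "no difference"). Coefficient covariance is
(XᵀWX)⁻¹ at the ML weights; γ-uncertainty is not propagated into the
mean-coefficient standard errors.

**Nonlinearity decision.** The cubic term is tested against the quadratic
model and the quadratic against the linear model by likelihood-ratio tests.
Two choices matter:

1. *Reference distribution.* The LR statistic is mapped onto
   F(q, n − k_full) via F = (exp(LR/n) − 1)(n − k_full)/q — the exact
   identity for nested least-squares fits — instead of the asymptotic
   chi-square, which is noticeably liberal at the study's n = 126 wells.
2. *Family-wise level.* Nonlinearity is declared when either term-wise
   p-value falls below α/2 (Bonferroni split), so the probability of
   declaring a truly linear curve nonlinear is held at the stated α = 0.05.
   An uncorrected either-rejects union of two α-level tests would operate
   near 2α and would not match the procedure's stated level.

Measured over 6,000 simulated truly-linear series, the empirical type-I
rate of this construction is ≈ 0.053.

**Linear-range loop** (`assess_linearity`):

1. drop concentrations at and below the highest level whose replicate SD
   around the level mean exceeds 1.5 Cp (the model-free per-level statistic;
   large residual variation at tiny inputs is the preamplification regime);
2. fit linear/quadratic/cubic and test as above;
3. when nonlinearity is significant, the best-fitting polynomial is the
   cubic if the cubic term is significant, else the quadratic; DL(x) =
   polynomial − linear prediction at each design level; while max |DL| ≥ 1
   Cp, remove the extreme level (lowest or highest concentration) with the
   larger |DL| and refit — removals only at the ends keep the retained
   range contiguous.

Fewer than 5 surviving levels yields a flagged "no valid linear range"
result rather than an exception. When nonlinearity is never significant no
DL is computed and the report shows an absent value (the table convention
for such genes). Note a sharp single-level Cp step cannot be chased by a
smooth cubic, so DL-based removal responds to smoothly accelerating
distortion (the physically expected low-input failure mode), while abrupt
single-level noise is the residual-SD rule's job.

**Efficiency** = 100·(2^(−1/slope) − 1), from the final linear fit's slope;
100% is perfect per-cycle doubling. The 95% CI transforms the slope's Wald
interval endpoints through this monotone map (the interval method for the
published per-gene CIs is not stated; Wald-from-slope is the natural
choice and is documented as ours). The cross-gene acceptance rule
"median ± 20%" is interpreted as absolute percentage points around the
median efficiency, matching how observed deviations are quoted (e.g.
"within ± 6.3% of that value").

**Accuracy.** Inverse prediction x̂ = 2^((Cp − b0)/b1) from the final
linear fit; per-level mean percent bias = 100·Σ(x̂ − x_k)/(m·x_k) over the
m valid wells at level k. The acceptance rule checks |bias| < 25% at the
design levels closest to the nominal, one-half and one-quarter qPCR inputs
(nominal 20 ng by default).

## Sensitivity (LOD / LOQ, Cp scale)

LOD: mean natural-scale expression u = 2^−Cp admits a finite
zero-concentration background plateau. The near-background region (levels
whose mean Cp lies within 6 Cp of the latest level mean, minimum 4 levels)
is fitted with `E[u] = β_bg + β_sig·x` by weighted least squares, weighting
level means by their empirical sampling variances; non-detect wells enter
as u = 0 (their signal is below 2^−45). LOD = −log2(lower one-sided 95%
bound on β_bg), reported at the cap (default 40 Cp, configurable) with a
`capped` flag when the bound is nonpositive or the Cp exceeds the cap. Two
deliberate choices: (i) the variance weighting is model-free rather than
propagated from the Cp-scale log-linear variance model, because that model
degenerates as x → 0, exactly where the plateau lives; (ii) a *lower* bound
on natural-scale expression maps to a *later* Cp, so noise pushes the
reported LOD toward the cap — which is why well-behaved, low-background
assays typically report the cap itself.

LOQ: x* = inverse prediction of y_min from the final linear calibration,
floored at the lower linear-range limit; LOQ = upper one-sided 95%
confidence limit of the fitted mean Cp at x*, using the heteroscedastic
fit's coefficient covariance and a normal quantile. y_min is not publicly
defined for this assay; the default is the gene's LOD (the detection
bound), overridable per gene in configuration. The per-gene LOD acceptance
rule is Cp > 35, strict.

## Precision and reproducibility

Balanced-design REML has closed forms identical to the ANOVA estimators:
for the precision model (random sample, fixed RNA input, no interaction)
σ̂_ε² = SSE/(N − I − J + 1) with SSE the two-way residual sum of squares,
and σ̂_α² = (MS_sample − σ̂_ε²)/(J·K); the reproducibility model uses the
one-way within/between decomposition with N − I residual dof. Unbalanced
data fall back to direct numerical optimization of the restricted
likelihood (per-sample block inverses via the Woodbury identity;
Nelder-Mead on log-variances with multiple starts). Negative
variance-component estimates are truncated at zero with a flag. The 95%
confidence limits on the residual SD use the chi-square interval on σ² at
the residual dof (the published tables' CI method is unstated; those CIs
are report-shape targets only). `variance_fraction(c, t) = 100·c²/t²`
expresses a component SD as a percent of total variance.

## Synthetic-data generators

All generators are pure functions of (parameters, seed); noise is Gaussian
on the Cp scale because every model above is Gaussian on Cp. Defaults
reproduce the validation-study conditions:

* dilution series: 14 two-fold levels from 204 ng/well (1,638 ng for the
  low-expressing TPX2 and SRD5A2), 3 series × 3 wells; slope −1.0468
  (93.9% efficiency); variance exp(γ0 + γ1 L) with γ0 = 2·ln 0.15 and
  γ1 = −0.15, so the noise SD grows from 0.15 Cp at 1 ng to ≈ 0.22 Cp at
  the lowest level; draws past 45 cycles are censored to NON_DETECT, never
  truncated. An optional background plateau saturates the mean via
  Cp = −log2(2^−poly + 2^−plateau). A fault-injection hook
  (`fault_bias`/`fault_levels_ng`, plus global `conc_bias`) mis-dispenses
  chosen levels for exercising the accuracy criteria;
* precision studies: 10 samples × {5, 10, 20} ng × 3 replicates from
  Y = μ + α + λ + ε with defaults σ_α = 11.4 (between-patient SD of the
  100-unit score), σ_ε = 1.86 (precision SD) and λ = (0, +1.22, −1.22),
  chosen so the pooled within+between-input SD is ≈ 2.11 (reproducibility);
  per-gene runs use the 0.1–0.2 Cp scale of normalized expression;
* control plates: per plate one positive-control pool in triplicate per
  gene, triplicate gDNA-positive wells, three no-template wells (always
  NON_DETECT); 18 plates give 54 Cp values per gene;
* RNA yields: lognormal with meanlog = ln 40, sdlog = 0.6 (per 0.0225 mm³
  of tumor, the smallest evaluable biopsy: 1 × 0.75 × 0.030 mm), placing
  the first quartile near 27 ng — inside the observed 19–34 ng band — and
  the mean below 50 ng. The published yield data are only quartile
  summaries, so these parameters are configuration, not claims.

What the generators do **not** emulate: plate-position and carry-over
effects, reagent-lot and operator shifts (precision draws are iid within
cells rather than crossed with instrument factors), non-Gaussian Cp-calling
artifacts near threshold, and preamplification chemistry. Passing tests
therefore demonstrate correctness of the estimators and procedures under
the stated statistical models, not robustness to real-plate artifacts.
`DilutionDesign.fold_range` follows the conventional one-log-unit-per-level
count (a 14-level two-fold series is quoted as 2^14 = 16,384-fold although
its endpoints are 2^13 apart).

## Problem sizes and numerical choices

Monte-Carlo checks in the test suite use 40–400 replicate studies (200–400
for mean-recovery and coverage claims, 1,000 series for the type-I
calibration of the nonlinearity test), sizes at which the Monte-Carlo
standard error is comfortably below each asserted tolerance. Optimizer
tolerances: 1e-8 on the 1-D variance profile; 1e-12/1e-13 (xatol/fatol) for
numerical REML. Ties in the DL-removal step break toward the
high-concentration end. Degenerate inputs (exactly constant data, zero
noise) are handled by the variance floor and the closed-form branches and
are covered by tests.

## Known limitations

* The published per-gene tables (efficiencies, linear ranges, LOD/LOQ,
  precision SDs) derive from unpublished raw plate data; they are used here
  as report schemas and plausibility regimes, not as reproduction targets.
* Efficiency and LOQ intervals ignore variance-parameter uncertainty
  (first-order Wald); the bootstrap cross-checks in the tests bound the
  effect at the study's design sizes.
* The LOD mean model is linear in concentration on the natural scale;
  strongly super-linear near-background responses would need the
  interface's alternative mean models.
* Numerical REML assumes a single random intercept (sample); crossed
  operator/instrument/lot random effects are out of scope.
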
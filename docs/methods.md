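# Methods

## Shared covariate design

Every engine is linear in the same design row.  Continuous covariates
enter as deviations from fixed centres — gestational age at delivery in
days from 280, maternal height in cm from 163, pre-pregnancy weight in
kg from 64 — each with linear, quadratic and cubic terms.  Fetal sex is
effect-coded (+1 male, −1 female), so the two sexes carry
equal-and-opposite coefficients and a profile with `sex="average"`
(code 0) describes a sex-marginal chart, the convention used in the
published worked examples this package reproduces.  Race/ethnicity
(NH-Black, Hispanic, Asian/Pacific-Islander against NH-White) and
parity (1 and 2+ against nulliparous; parities of two or more share one
group) are dummy-coded.  At the reference profile every non-intercept
physiologic column is zero, so a fitted intercept *is* the term optimal
weight (TOW) there.

Five "pathologic" covariates — smoking, BMI, gestational diabetes, any
hypertensive disease, antepartum bleeding — are included at fit time so
the physiologic coefficients are estimated net of them, but their
contributions are zeroed in every chart prediction: the chart describes
the growth potential of a healthy pregnancy with the profile's
physiologic characteristics.  BMI enters linearly in kg/m², centred at
the training cohort's mean so the intercept remains the reference TOW
(the alternative categorical coding was considered and rejected as it
adds boundary artefacts without changing any chart value; the centre is
recorded in the fitted design).  Hypertensive disease collapses to a
single any-hypertension indicator.  Records missing any of the six
physiologic covariates are excluded (complete-case analysis, with a
row-indexed exclusion log); missing pathologic flags are treated as
absent with a warning.

## Constant-CV engine

OLS over the full design; residual SD from the usual n−p denominator.
The chart assumes birthweight normal around the customized TOW with SD
proportional to it: `P_q = TOW·(1 + z_q·CV)`.  The CV defaults to the
pooled residual SD over the mean predicted TOW of the training cohort,
with an override hook for an externally specified population constant
(the published study population's 0.129).  The z multipliers default to
the truncated two-decimal values used in published chart arithmetic
(±1.28 for the 10th/90th, ±1.645 for the 5th/95th — the latter are not
printed in the source material and follow the same truncation
convention); a `z_mode="exact"` switch uses full-precision normal
quantiles.  Chart outputs round to integer grams; internal arithmetic
is unrounded.

## Heteroscedastic engine

The normal model `y ~ N(x'β, σ₀²·exp(z'γ))`, where z is the design
without its intercept; σ₀ is reported on the SD scale in grams while γ
are log-variance-scale slopes — the hybrid parameterization in which
the published variance tables and worked sigma examples are written, so
both are directly checkable.  The variance design mirrors the mean
design column-for-column by default (`variance_pathologic=False` drops
the pathologic columns from the variance part only).

Fitting alternates (i) weighted least squares for β at weights 1/σᵢ²
and (ii) one Fisher-scoring step for (α=log σ₀², γ) with score
−½·Σ zᵢ(1 − eᵢ²/σᵢ²) and expected information ½·Z'Z, halving the step
until the exact log-likelihood does not decrease.  Convergence:
relative log-likelihood change below 1e-8, at most 200 iterations
(non-convergence raises, carrying the trace); β initialized at OLS, γ
at 0, σ₀ at the OLS residual SD.  The trace is monotone by
construction and asserted in tests.  Standard errors come from the
block-diagonal expected information at the optimum — (X'WX)⁻¹ for β,
2(Z'Z)⁻¹ for (α, γ), delta method for σ₀.

Two numerical guards address genuine degeneracies of log-linear
variance models.  A binary variance column whose minor group has fewer
than 10 members is excluded from the variance design (with a warning):
such a column lets the likelihood grow without bound by driving that
group's σ toward zero.  Independently, per-observation log-variance is
floored 16 nats below its homoscedastic initial value; the floor
becoming active triggers a warning rather than silent truncation.

Percentiles: `P_q = TOW + z_q·σ(profile)`, with pathologic columns
zeroed in both the mean and the sigma, matching the published
worked-example arithmetic (our evaluation of the printed coefficients
reproduces the published sigmas to ≤ 0.01 g and percentiles to ≤ 1 g,
the residue of printed-coefficient rounding).

## Quantile-regression engine

For each τ the coefficient vector minimizes the check loss, solved
exactly as the standard LP primal (min τ1'u + (1−τ)1'v subject to
Xβ + u − v = y) with scipy's HiGHS solver — deterministic for a fixed
row order.  Degenerate optima are possible (duplicated rows may select
a different vertex of the same optimal face); the package asserts
loss-optimality, not coefficient uniqueness.  Standard errors for the
median fit use the iid sparsity estimate with a Hall–Sheather
bandwidth.  Predictions from separately fitted τ-planes can cross at
extreme profiles; `predict_quantiles` applies monotone rearrangement —
the predicted values at a profile are sorted and reassigned to the
ascending τs — which is idempotent and order-preserving.  A
joint non-crossing-constrained fit was considered out of scope; the
rearrangement is this package's documented smoothing device, not a
claim about any other implementation.

## Gestational extrapolation

A term percentile is scaled to gestational age t by a proportionality
curve normalized so proportion(280 d) = 1 exactly (term extrapolation
is the identity).  The shipped default is the classical cubic
percent-of-term curve in gestational weeks (Gardosi et al. 1995),
renormalized at 280 days; both the curve and the estimated-fetal-weight
(EFW) biometry formula — default the Hadlock 1985 three-parameter
log10-linear model in HC/AC/FL (cm) — are labelled JSON configuration,
not hard-coded constants, because they originate outside the coefficient
tables this package reproduces and users may substitute local
references.

Rolling paired-week refits check the variance model across gestation:
the heteroscedastic engine is refitted on EFW within half-open windows
[w, w+2) completed weeks for w = 21, 22, …, so every visit lands in one
or two windows.  Within a 14-day window the cubic GA polynomial is not
identifiable, so the window design keeps a linear GA term centred at
the window midpoint and drops pathologic adjusters; dummy columns with
no variation inside a window are dropped per window, and windows with
fewer usable visits than design columns are skipped with a log entry.
Repeated visits of one pregnancy within a window are all used without a
within-mother correlation adjustment — per-pair coefficient SEs are
therefore mildly optimistic (documented limitation).

## Diagnostics

Deliveries are sorted by predicted TOW and cut into eight contiguous
equal-length (not equal-count) intervals, rightmost closed, so the
partition is exhaustive; extreme strata are naturally sparse.  Per
stratum: empirical mean, SD (reported only for n ≥ 2) and percentiles
of observed birthweight (linear interpolation of order statistics —
numpy's default, type 7; the convention matters only in tiny strata),
against the within-stratum mean of each record's model percentile.
The CV-constancy check regresses stratum SD on stratum mean TOW, both
free and through the origin (the through-origin slope estimates the CV
when proportionality holds; both are reported since constraining the
line is itself an assumption).  The percentile-agreement table reports
empirical − model differences in grams: positive at a high quantile
means the model under-estimates that percentile.  Residual QQ uses
per-record standardization (customized σᵢ under the heteroscedastic
engine, pooled SD otherwise) with a Shapiro–Wilk statistic reported but
no accept/reject decision; constant residuals are flagged degenerate.

## Screening evaluation

SGA is birthweight strictly below the chart's 10th percentile at the
delivery's own profile; LGA strictly above the 90th (ties are not
flagged, following the strict printed definitions).  A pluggable
GA-by-sex lookup supports external population references.  The 2×2
machinery reports sensitivity, specificity, PPV, NPV; odds ratio with
Woolf's log-scale CI (0.5 continuity correction only when a cell is
zero, with a warning); and the c-statistic in its rank (Mann–Whitney)
form with a Hanley–McNeil CI — for a binary classifier this equals
(sens+spec)/2, an identity asserted in tests.  The logistic-regression
hook (IRLS via iteratively reweighted least squares, tolerance 1e-10)
defaults to the unadjusted binary-exposure model, whose OR matches the
2×2; covariate adjustment is available through the design argument.
Complete separation raises an error naming the separating column.
Composite neonatal morbidity is an any-of aggregation over a component
list with SGA-specific (periventricular leukomalacia, culture-positive
sepsis, BPD/chronic lung disease, retinopathy) and LGA-specific (birth
injury) members; absent component columns count as false and are
logged.

## Synthetic cohort generator

The generator defines the package's study conditions: covariate
marginals follow the published cohort summary (height 162.8 ± 7.0 cm;
weight 67.4 ± 14.9 kg truncated to [40, 130]; race 28.1/26.5/29.1/16.3%
for NH-White/NH-Black/Hispanic/Asian-PI; parity 46.4/34.6/19.0% for
0/1/2+, the 2+ group mixing real parities 2 and 3; 50.8% male; delivery
GA 39.5 ± 1.1 weeks truncated to 37–41 completed weeks and converted to
whole days), and birthweight is drawn from the heteroscedastic truth at
the published coefficient tables (σ₀ = 374.5975 g and the printed γ).
Covariates are drawn independently — only marginals are emulated.
Consequences for interpretation: passing recovery and self-consistency
tests demonstrate correctness of the estimators under the stated model,
not robustness to real-world covariate correlation, site effects,
measurement error in GA dating, or selection, none of which the
generator represents.  BMI is derived exactly as weight/height², so the
BMI column is a deterministic function of two physiologic covariates;
recovery experiments therefore fit the matched physiologic-only model
(in real data, measured BMI is not exactly collinear).  One further
printed-value note: the published worked sigma formula contains a term
"+0.0236·(0)" that matches no printed variance row; since its covariate
is zero at every published profile it cannot affect any reproducible
value, and it is omitted from the shipped coefficient set (the sex
variance coefficient uses the printed 0.025).

Morbidity flags are Bernoulli with
logit p = logit(base 0.04) + log(2.05)·SGA_true + log(1.80)·LGA_true,
where true status comes from exact normal quantiles of each record's
own generating distribution; morbid deliveries receive one or two
random component flags so composite aggregation is exercised.  Because
LGA also raises morbidity among SGA-negatives, the marginal 2×2 SGA
odds ratio is attenuated below 2.05 under the defaults; round-trip
checks of the OR therefore switch the LGA odds to 1, making the 2×2
estimand exactly the configured value.  Longitudinal visits follow the
study schedule (±1 week jitter) with EFW = proportion(GA)·true term
mean plus proportional noise; an optional effect-switch week zeroes the
maternal-height contribution before that week, providing a built-in
oracle for trend detection in the paired-week analysis.

All randomness flows from `numpy.random.default_rng(seed)`; one config
maps to one byte-identical cohort.

## Problem sizes and test design

Desk-scale checks evaluate printed coefficients in closed form
(tolerances ±2 g for weights, ±0.5 g for sigmas, absorbing
printed-coefficient rounding).  Simulation checks use sizes chosen for
tight-but-fast Monte-Carlo error: parameter recovery averages 50
cohorts of n = 5000 (σ₀ mean bias within 2%, weight-γ within 10% of
truth); self-consistency of the diagnostics runs 20 seeds per engine at
n = 1500–2000 and requires the seed-averaged, bin-size-weighted
empirical−model percentile difference to sit within Monte-Carlo error
of zero (4 standard errors, with a 10 g floor covering the small-sample
bias of extreme empirical percentiles in strata of a few hundred).
Oracle equivalence pits the alternating ML fit against a derivative-free
dense optimizer of the same likelihood on n = 50 (≤ 1e-4 relative
log-likelihood) and the quantile LP against a coefficient grid on tiny
instances.

## Known limitations

- Independent covariate draws in the generator (above).
- The quantile engine ships SEs only for the median, via the iid
  sparsity estimate; no bootstrap bands.
- Paired-week fits ignore within-mother correlation.
- The proportionality curve and biometry formula are external reference
  data; their defaults are reasonable but site-specific practice varies.
- No imputation: complete-case physiologic covariates only.
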
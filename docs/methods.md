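# Methods

`rfjem` implements a job-exposure-matrix (JEM) analysis of occupational
radiofrequency electromagnetic-field (RF-EMF, 100 kHz–300 GHz) exposure and
brain-tumor risk in a stratified case-control design: linkage of a JEM to
lifetime job histories, cumulative and time-weighted-average (TWA) exposure
metrics over lags and time windows, percentile-based categorization anchored
in the control distribution, and odds-ratio estimation by exact conditional
logistic regression.  This note records the model, its conventions, the
numerical choices, and what the synthetic data do and do not establish.

## Exposure model

**Intensity.**  The matrix assigns each 4-digit ISCO88 occupation code and
field kind (electric E in V/m, magnetic H in A/m — assessed independently
because they decouple in near-field conditions) a dimensionless intensity:
the time-weighted-average squared ratio of the mean field level to the
frequency-specific occupational reference level,
`(Ḡ_s(f) / G_RL(f))²`, which is proportional to the specific absorption
rate above 100 kHz.  The package treats the matrix as already aggregated to
one intensity and one exposure prevalence per (code, field): combining
source measurements across frequency bands, distance and shift-time
modifiers is upstream of this package.  The squared-ratio primitive is
exposed (`icnirp_squared_ratio`) so synthetic matrices can be built from
synthetic source measurements.

**Linkage methods.**  Three increasingly specific rules attribute matrix
intensities to job spells: M1 links every occupation carrying exposure in
the matrix; M2 additionally requires the occupation's exposure prevalence
to be at (or above) the median prevalence among exposed occupations — the
comparison is inclusive (`>=`), so an occupation exactly at the median
stays exposed; M3 links only jobs in which the participant reported RF-EMF
source use.  By construction the exposed sets nest: M2 ⊆ M1 and M3 ⊆ M1.

**Year conventions.**  The finest time unit is one calendar year (job
dates are collected in years; sub-year durations are not modelled).  A
spell covers years `start..end` inclusive.  Years covered by several
concurrent spells take the arithmetic mean of the concurrent spell
intensities, with unexposed spells entering as zeros.  Cumulative exposure
under lag L sums the yearly series over years `<= ref − L`; the window
(a, b) sums over `[ref − b, ref − a]`.  These bounds make

    cumulative(lag 1) = window(1–4) + window(5–9) + cumulative(lag 10)

an exact partition, which the tests assert to 1e-9 (the slack covers
summation-order float effects only).  TWA divides cumulative exposure by
the number of years *worked* (any spell, including nonstandard periods) in
the same span, 0 when none; the alternative reading "years exposed" was
considered and rejected because unexposed employment is informative
person-time in this design.

**Reference dates.**  Cases anchor at the diagnosis year; controls at the
interview year minus the cases' median diagnosis-to-interview gap
(computed per tumor type, pooled across countries, rounded half-up to a
whole year).

## Exclusions

The ordered cascade removes participants with (1) uncertain/unknown source
information or no occupational history, (2) missing education,
(3) chronological problems (unknown years, end before start), (4) a
history consisting solely of nonstandard occupations (housewife/husband,
pensioner, training, imprisonment), and (5) any unknown occupation code.
A participant is counted once, under the first criterion matched; the
order follows the narrative order of the study's accounting and is made
auditable by the `ExclusionLedger`, whose conservation (initial = final +
Σ excluded, per group) is checked on every run.  Nonstandard spells held
alongside real jobs are retained as unexposed periods.

## Categorization

Cut-points are the 50th/75th/90th percentiles of the exposure distribution
among *exposed* controls (the never-exposed form the reference group, so
they are excluded from the percentile basis; a config flag can include
zeros as a robustness check).  Quantiles use linear interpolation between
order statistics.  Values exactly at a cut-point fall in the lower
category.  Cut-points are computed independently per analysis cell
(metric × label × method × field), from that run's included controls —
they are recomputed after any sensitivity filter that changes the control
set.  A sensitivity variant rebases the reference on the low-exposed
category; this is a pure relabelling, and with saturated category
indicators the rebased contrasts equal ratios of the primary contrasts at
the optimum (tested numerically).

## Conditional logistic regression

Strata are the cross-classification of the matching factors (5-year age
band × sex × country/region); models adjust for education (two indicators,
high-school-or-less as reference).  The exact conditional likelihood is
used because pooled matching can put many cases in one stratum, where the
Breslow approximation degrades; Breslow remains available by config and
coincides with the exact likelihood for 1:1 matched pairs (tested).

The stratum denominator — the sum of `exp(Σ η)` over all case-sized
subsets — is evaluated by the elementary-symmetric-function recursion
`f(j, r) = f(j−1, r) + f(j−1, r−1)·exp(η_j)`.  The fitter carries the
recursion in linear space together with the subset-weighted sums of `x_S`
and `x_S x_Sᵀ`, yielding log-likelihood, score and observed information in
one pass; linear predictors are centered within stratum (the likelihood is
shift-invariant, tested) and accumulators are rescaled when they leave
`[1e−250, 1e250]`.  The public `stratum_loglik` takes an independent
log-space forward–backward route (prefix/suffix subset-sum tables,
inclusion probabilities via `logsumexp`), stable for strata of any size;
the two routes are cross-checked against exhaustive subset enumeration.

Newton–Raphson starts at zero with step-halving; convergence requires a
relative log-likelihood change below 1e-8 and maximal absolute score below
1e-6, within 50 iterations.  Strata with zero cases or zero controls are
non-informative and dropped with a logged count.  Separation is reported,
never silently estimated: a fit whose coefficients exceed 10 in absolute
value is flagged as monotone-likelihood and non-converged (a log odds
ratio beyond ~10 is an artifact in this design), and `odds_ratios`
refuses non-converged fits.  Confidence intervals are Wald intervals with
the 1.96 normal quantile; no small-sample correction.  The trend test
replaces the four category indicators by one ordinal score (0–4, counting
the unexposed level) and reports the Wald p-value; a score with no
within-stratum variation carries no conditional information and returns
p = 1 by symmetry.

## Synthetic data

The generator emulates the study setting the pipeline targets, at the
published marginal structure: 468 occupation codes with 62% carrying
exposure; job-level exposure prevalence Beta(1, 19) (mean 5%, median ≈
3.6%); yearly intensities lognormal(−0.3, 1.2) with E/H log-correlation
0.92 (Spearman ≈ 0.9); interviews 2000–2004; control-like age/sex/country
margins; careers averaging ≈27.6 years from workforce entry around age
16–24, with a mean of 4 jobs, occasional gaps, overlaps and nonstandard
periods; case:control ≈ 1:1.5.  Commonly held occupations skew toward low
exposure prevalence (weight `exp(−22·prevalence)` within exposed codes),
which reproduces the observed pattern that nearly all participants hold
some nominally exposed job (M1 ≈ 90% exposed) while the
prevalence-restricted and self-report methods are far more specific
(M2 ≈ 35%, M3 ≈ 8–12%).  Source-report flags are noisy observations of
true job-level exposure with sensitivity 0.90 and specificity 0.97,
operationalizing recall error.  Configured fractions of participants are
mutated to violate each exclusion criterion (defaults at the published
control rates).

Disease status is drawn from a logistic model in the exposure category of
a configurable metric (default: cumulative, all-jobs linkage, E field,
1-year lag) with configurable per-category log odds ratios, stratum
effects N(0, 0.2), and an intercept solved so the expected case fraction
matches the configured ratio.  The effect is defined at reference year =
interview − 1, which is what the analysis reconstructs at the median
diagnosis-interview gap.  The truth record carries each participant's
generative category and stratum, so recovery tests evaluate the estimator
against the exact covariate that generated the outcome.

What the synthetic data do *not* establish: parameter-recovery tests fit
on the truth categories; re-deriving categories through control-based
cut-points (as the full pipeline does on real data) adds boundary
misclassification that attenuates extreme-category contrasts by roughly
10% relative in this configuration — an expected property of
percentile-categorized exposure, not a defect of the estimator.  The
generator also ignores country-specific labor markets, real occupation
frequency distributions, and within-job intensity variation; passing tests
demonstrate correctness of the accounting and estimation machinery, not
epidemiological realism.

## Problem sizes

Simulation-based checks use: exposure-accounting identities on a cohort of
~1,030 participants across all methods, fields, and the five primary
labels; parameter recovery on 500 cohorts of ~2,000 subjects (true OR 1.5
on the top category); trend-test calibration on 1,000 null cohorts of 600
subjects.  The acceptance script reports the same quantities from 150
recovery and 400 calibration replicates, sized to keep a single-CPU run
short while leaving Monte-Carlo error well inside the bands of interest.

## Known limitations

- The matrix is an input; building it from source-exposure measurements
  (combination weights, confidence ratings, distance/time modifiers) is
  out of scope.
- Exposure is annual; hours-per-week weighting and peak-exposure metrics
  are not modelled.
- No multiple-testing adjustment across the analysis grid (matching the
  reporting convention of the design this mirrors); the grid emits
  unadjusted Wald CIs per cell.
- The Breslow option is provided for comparison only; all defaults use the
  exact conditional likelihood.
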
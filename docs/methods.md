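# Methods

## Response families

Four families serve as chart response distributions, in their standard
"original" (positive-μ, log-link) parameterizations.

**Box–Cox families (BCCGo, BCPEo).** The transform
z = ((y/μ)^ν − 1)/(νσ) (log branch at ν = 0, taken when |ν| < 1e−7;
continuity at the switch is verified to 1e−6) maps (0, ∞) onto a
half-bounded interval whenever ν ≠ 0.  The latent distribution is the
standard normal (BCCGo) or the variance-standardized power exponential
with shape τ (BCPEo; τ = 2 recovers the Gaussian, so BCPEo(τ=2) ≡ BCCGo
pointwise).  The latent density is always renormalized over the
attainable z-range by the factor F_lat(1/(σ|ν|)); `truncation_mass`
exposes the excluded mass so callers can verify it is negligible (it is
below 1e−6 for all parameter regions the charts actually visit).  μ is
then the exact median up to that truncation, and σ approximates the
coefficient of variation.

**Skew exponential power families.** SEP1 is the Azzalini-type form
f(z) ∝ f₁(z)·F₁(νz) with f₁ the power exponential PE2(0, τ^{1/τ}, τ);
SEP3 is the two-piece form with scale ν on the left of μ and 1/ν on the
right.  Both have support on the whole real line; they are used for
positive data whose fitted densities put negligible mass below zero, and
`truncation_mass` reports that sub-zero mass as the analogous diagnostic.
Symmetry points: ν = 0 (SEP1) and ν = 1 (SEP3).  The two symmetric
reductions use different scale conventions (τ^{1/τ} vs 2^{1/τ}), as in
the published forms, so they are not numerically identical to each other.

CDF/quantile evaluation is closed-form for the Box–Cox families and SEP3
(incomplete-gamma identities); SEP1 uses adaptive quadrature for the CDF
and bracketed root-finding (tolerance 1e−12) for the quantile.  Sampling
is inverse-CDF everywhere except SEP1, which uses exact rejection from
its symmetric envelope (acceptance rate exactly 1/2).  All sampling is
driven by `numpy.random.Generator` seeds and is bit-reproducible.

## LMS fitting

`fit_lms` maximizes the penalized log-likelihood
Σᵢ log f(yᵢ; θ(tᵢ)) − ½ Σ_θ λ_θ γ_θᵀ D₂ᵀD₂ γ_θ over the coefficient
vectors of per-parameter curves η_θ(t) = B(t)γ_θ, with log links for μ,
σ, τ and an identity link for ν (log for SEP3, whose skew parameter must
stay positive).  The optimizer is cyclic backfitting: for each parameter
in turn, a Fisher-scoring step built from central-difference first and
second derivatives of the per-observation log-likelihood with respect to
η (step 1e−4, curvature clipped to [1e−6, 1e8]), followed by step-halving
so the penalized objective never decreases.  Convergence is declared when
the objective changes by less than 1e−4 between cycles (cycle budget
1000); the per-cycle objective path is stored in `fit_meta` and is
asserted non-decreasing by the test suite.  On a joint test problem the
backfit reproduces a direct joint maximization of the same likelihood to
10 significant figures.

Curve flexibility is expressed in effective degrees of freedom: edf 1 is
a constant, edf 2 an exact linear trend, and edf ≥ 3 a cubic B-spline
(interior knots at quantiles of t, basis size edf + 3) with a
second-difference (P-spline) penalty whose λ is recalibrated during the
first cycles to hit the edf target via the generalized eigenvalue profile
of (BᵀWB, D₂ᵀD₂).  Defaults: edf grids {2..6} for μ, {2,3,4} for σ, {1,2}
for ν and τ; grid selection is a coordinate search (at most two sweeps,
fits cached) minimizing AIC = −2·logL + k·Σedf with k = 2.  Reported edf
are recomputed at the final weights.  BCCGo fixes τ = 2 and contributes
no edf for it.  No transformation is applied to the age covariate.

Initialization is deterministic: μ from a (penalized) least-squares fit
of log y, σ from the log-residual spread (raw-residual spread for the SEP
location-scale families), ν at its family's no-skew/no-transform value
(1 for Box–Cox, 0 for SEP1, 1 for SEP3), τ at 2.

## Quantile-regression comparator

Each quantile level q is fitted by minimizing the check loss
Σ ρ_q(yᵢ − xᵢᵀβ), cast exactly as a linear program (HiGHS); the
"lasso" solver adds penalty·‖β₋₀‖₁ to the LP objective (intercept
unpenalized, default penalty 1).  Bases: linear, raw polynomials of
degree 2–4 on the standardized covariate, a natural cubic spline with
five quantile knots, and a six-column cubic B-spline.  Levels default to
the chart centiles {3, 10, 25, 50, 75, 90, 97}%.

Because quantile regression has no likelihood, AIC uses the
asymmetric-Laplace surrogate per level:
logL_q = n(log(q(1−q)) − 1 − log(mean check loss)), AIC_q = 2p_q − 2·logL_q
(p_q = basis dimension; nonzero count for the lasso).  Per-level values
and their sum are both reported; the headline `aic` used in model
selection is the per-level **mean**, which is the scale comparable to a
single density fit — summing over levels would penalize the QR path
merely for being evaluated at more levels.  Fitted per-level curves may
cross in raw form; `predict_non_crossing` offers a post-hoc monotone
rearrangement, off by default in all outputs.

`select_best_model` takes any mix of LMS and QR candidates, drops
non-converged ones with a warning, and returns the AIC argmin (ties:
fewer edf, then declaration order) plus the full comparison grid.

## Centile tools and calibration

Centile curves, individual centiles (100·CDF) and Z-scores (Φ⁻¹∘CDF) all
evaluate the fitted parameter curves inside the fitted age range;
extrapolation requires an explicit flag and is warned about.  CDF
over/underflow clamps Z at ±8 with a warning.  Calibration reports, per
target centile α ∈ {1, 3, 10, 25, 50, 75, 90, 97, 99}%:

* predicted coverage — the share of cases strictly below their
  age-specific fitted curve (ties count as not-below; a measure-zero
  choice fixed for reproducibility);
* observed coverage — the share of cases strictly below the *empirical*
  α-quantile of the sample (linear-interpolation convention, the same
  quartile convention as QC), i.e. the attainable coverage of a perfectly
  calibrated chart at this n; for non-integer rank positions this equals
  100·⌊1 + α(n−1)⌋/n.

Both are rounded to 2 decimals in reports; gaps use unrounded values.
Z-score diagnostics report moments plus the D'Agostino normality test.

## Precision arithmetic

SE_p = SD·√((1 + Z_p²/2)/n) for the p-th centile, inverted as
n = ⌈SD²(1 + Z_p²/2)/SE²⌉.  The printed source formula is typographically
ambiguous; this reading is adopted because it alone reproduces both
published worked values (n = 1169 at SE 0.05; SE 0.03 at n = 2547).  The
SD = 1 premise comes from `boxcox_standardize`: a maximum-likelihood
one-parameter Box–Cox transform, centered and scaled to unit sample SD,
with a normality statistic attached.  Selection among wider
transformation families is out of scope.

## Quality control

Dice triage flags pairs of independent segmentations in three sequential
rounds (placenta < 0.60; placenta < 0.75 and fluid < 0.40; fluid < 0.40),
first match wins, missing values flagged unresolvable.  All thresholds
are strict inequalities.  Volume outliers use per-gestational-day Tukey
fences Q1 − 1.5·IQR / Q3 + 1.5·IQR with linear-interpolation quartiles
(the mainstream statistical-software default; the convention materially
changes flags at small n, so it is recorded in the report).  Day groups
under 4 observations are exempt and logged; boundary values are retained.

## Synthetic cohorts

The generator emulates the statistical structure the charts assume — not
ultrasound physics.  Defaults: n = 2500; gestational ages on the integer
days 79–99 with truncated-normal weights peaked at day 89 (SD 4.5 days),
reproducing scarce data at the age extremes; five perfusion series drawn
from BCPEo truths with linear-in-age parameter curves
(μ ranging ~0.06–0.26 across series, σ ~0.35–0.60, Box–Cox power ν < 1
everywhere to give positive skew, strongest in series 4, τ = 2); values
outside (0, 1) are resampled so fractions stay physical.  Placental
volume is log-normal about a GA-increasing geometric mean (~60 ml at day
79, slope 0.025/day, log-SD 0.35), with a 0.6% injection of high-side
outliers at ~8× the day's geometric mean — the upper Tukey fence under
this spread sits near 2×, so injected outliers are genuinely
fence-busting.  Injection is high-side only: the lower fence of a
right-skewed volume distribution is near or below zero, so no positive
value can reliably bust it.  Dice values are high-agreement Beta draws
with rare injected failures per triage round (1%/0.5%/1%).  Outcome
flags are independent Bernoulli draws (smoker 1.81%, previous
pre-eclampsia 1.57%, preterm 6%, diabetes 4%, hypertensive disease 5%,
miscarriage 0.8%, stillbirth 0.3%, ...), with birth-weight and Doppler
centiles uniform on (0, 100) as population centiles are by construction;
2% of records have the birth-weight centile masked to exercise the
incomplete-outcome route.  Regeneration with the same spec and seed is
bit-identical.

What this does *not* emulate: correlation among outcome flags, between
perfusion series, or between perfusion and outcomes; measurement error;
site or operator effects; digit preference.  Passing tests therefore
demonstrate that the statistical machinery is correct under its own
assumptions, not that those assumptions hold in any real cohort.

## Pipeline and problem sizes

The orchestrated run applies outcome exclusions (any-match, with a
first-match flowchart ledger as well), then QC, then per-series candidate
fitting and AIC selection, and writes all artifacts as delimited text or
sorted-key JSON so reruns are byte-identical.  Standard hypothesis tests
in the excluded-case comparison (Wilcoxon rank-sum, Fisher's exact) are
delegated to scipy, with no multiplicity adjustment.  The fitted response
families place a small amount of probability above the physical bound of
1; the pipeline surfaces this as a `tail_mass_above_1` diagnostic
(typically < 1e−5) rather than truncating the family.

Problem sizes used in the shipped checks: distribution oracles run on a
10-configuration parameter grid with 50 000-draw Monte-Carlo samples;
parameter recovery uses 20 cohorts of n = 2500 (interior ages 84–94 days
for error summaries, where the age weights put adequate data); the
acceptance script runs one full pipeline at n = 2500 over two series with
all four families and eight QR configurations.

## Known limitations

* SEP1's CDF is quadrature-based and therefore the slowest path
  (~10–15 s per full fit at n = 2500); the closed-form families dominate
  in practice.
* The edf coordinate search can stop at a local grid optimum; with the
  default grids and smooth truths this has not been observed to matter.
* Charts are univariate in gestational age; no covariates, no bootstrap
  bands, and no extrapolation beyond the fitted age range.
* The measurement lives in (0, 1) but the families are supported on
  (0, ∞) (or ℝ); the mismatch is surfaced as a diagnostic, not resolved.
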
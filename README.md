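# placentile

Age-conditional reference charts ("centile charts") for first-trimester
placental perfusion measurements, built the way modern growth standards
are: skew four-parameter response distributions whose parameters vary
smoothly with gestational age, fitted by penalized maximum likelihood and
selected by AIC against quantile-regression comparators.

The motivating measurement is three-dimensional single-vessel fractional
moving blood volume (3D-svFMBV) — a power-Doppler-derived perfusion
fraction in (0, 1) evaluated at five locations within the uteroplacental
vasculature, scanned at 79–99 days' gestation (11+2 to 14+1 weeks).
These values are strongly positively skewed, their spread and shape drift
with gestational age, and healthy-cohort reference ranges for them are the
prerequisite for using perfusion Z-scores in screening research.  The
package is aimed at researchers building or recalculating such charts:
everything from cohort exclusion rules to the individual-centile
calculator is scriptable.

## The model

For a measurement *y* at gestational age *t* (days), the LMS/GAMLSS path
models the full conditional distribution

  y | t  ~  D(μ(t), σ(t), ν(t), τ(t)),

where *D* is one of four skew families — Box–Cox Cole–Green (BCCGo),
Box–Cox power exponential (BCPEo), and skew exponential power types 1 and
3 (SEP1, SEP3) — and each parameter curve is a cubic P-spline (log link
for μ, σ, τ) fitted by cyclic penalized maximum likelihood
(Rigby–Stasinopoulos-style backfitting).  Smoothness is chosen on an
effective-degrees-of-freedom grid by AIC = −2·logL + k·edf (default k = 2).
For the Box–Cox families the latent transform is the classical LMS
z-score

  z = ((y/μ)^ν − 1) / (νσ),  with z = log(y/μ)/σ at ν = 0,

renormalized for the truncation the transform induces.  Centile curves
are C_α(t) = Q(α; μ(t), σ(t), ν(t), τ(t)); an individual's centile is
100·F(y; t) and their Z-score is Φ⁻¹(F(y; t)).

The comparator path fits per-quantile curves by exact L1 (check-loss)
linear programming or lasso-penalized quantile regression over linear,
polynomial, natural-spline and B-spline bases, with an
asymmetric-Laplace AIC surrogate so both paths can sit in one AIC table.

The package also implements the surrounding epidemiological machinery:
healthy-cohort exclusion rules (miscarriage/stillbirth/preterm
definitions, fetal growth restriction from birth-weight and Doppler
centiles, maternal conditions), segmentation QC (Dice triage rounds,
per-day Tukey-fence volume outliers), centile-precision sample-size
arithmetic, and a synthetic-cohort generator so the entire pipeline is
testable without patient data.

## Worked example

```bash
# a synthetic screening cohort of 200 pregnancies
placentile simulate --n 200 --seed 2 --out cohort.tsv

# healthy-cohort exclusions, then fit a BCPEo chart to one series
placentile filter --cohort cohort.tsv --out included.tsv --ledger ledger.json
placentile fit --cohort included.tsv --series svfmbv1 --out model.json

# where does a measurement of 0.18 at 12+5 weeks sit?
placentile centile --model model.json --ga 12+5 --value 0.18
```

prints

```
included 147 / 200 records
BCPEo: loglik=183.54 edf=7.00 aic=-353.08
centile=46.52 z=-0.087
```

meaning 53 of the 200 simulated pregnancies met an exclusion criterion;
the fitted four-parameter model spent 7 effective degrees of freedom; and
a perfusion fraction of 0.18 at 12+5 weeks lies on the 47th centile of
the healthy reference (Z = −0.09), i.e. unremarkable.  The sample-size
arithmetic is available directly:

```bash
$ placentile precision --target-se 0.05
required n = 1169
$ placentile precision --n 2547
SE = 0.0339
```

`placentile run` executes the whole pipeline (filter → QC → all LMS and
QR candidates → AIC selection → charts, calibration tables, Z-scores) and
writes every artifact as delimited text / JSON.

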
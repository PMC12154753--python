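# spirolms

Spirometric reference equations via GAMLSS/LMS: z-scores, centiles,
equation refitting and population-suitability validation.

## The problem

Interpreting a spirometry test means comparing a subject's measured
indices — FEV1, FVC, FEV1/FVC and FEF25–75 — against the distribution
of values in healthy people of the same sex, age and height. Reference
equations encode that distribution; picking one that does not match the
local population biases every diagnosis built on it. This package
implements the full workflow used to build and judge such equations:

* **Distribution machinery.** Healthy spirometric indices are positive
  and right- or left-skewed, so the reference distribution is modelled
  with the Box-Cox Cole–Green family (BCCG — the LMS method: median
  *M*, coefficient of variation *S*, skewness power *L*) or its
  kurtosis extension, the Box-Cox power-exponential (BCPE). For a
  measurement *y* with subject-specific parameters (μ, σ, ν):

  z = ((y/μ)^ν − 1) / (νσ),  or  z = ln(y/μ)/σ when ν = 0,

  and BCPE maps the transformed value through the standardized
  power-exponential CDF with kurtosis τ (τ = 2 recovers BCCG). Centiles
  invert the map; the 5th centile is the lower limit of normal (LLN).

* **A packaged equation set.** The Iraqi Spirometric Equations (ISE) —
  sex-specific BCCG/BCPE models whose parameters are linear in
  ln(height) and ln(age) on identity or log links — ship as versioned
  JSON. Any competing set (e.g. GLI-style equations) can be supplied in
  the same schema and compared. The published ISE declare age splines on
  several μ/σ models without publishing their shapes, so the packaged
  files carry empty spline tables behind an explicit acknowledgement
  flag; refitting can populate them.

* **Refitting.** A GAMLSS-type fitter (Rigby–Stasinopoulos backfitting:
  penalized weighted least squares per distribution parameter, P-spline
  age smooths, effective df by smoother trace) refits any candidate
  model to cohort data; candidates are ranked by the Schwarz Bayesian
  criterion, SBC = −2·loglik + df·ln(n), with near-ties resolved toward
  fewer degrees of freedom and a residual-moment screen.

* **Validation.** Given an independent cohort, per-index summaries of
  predicted value, percent predicted (100·measured/predicted) and
  z-scores; the population-suitability rule |mean z| < 0.5; ranking of
  competing equation sets by |mean z|; Mann–Whitney U (midranks, exact
  enumeration for small samples), Kolmogorov–Smirnov normality and the
  minimum validation-sample rule (≥300 subjects, ≥150 per sex).

* **Synthetic cohorts.** A seeded generator reproduces the study
  population's structure — right-skewed adult ages, sex-specific
  heights, outcomes drawn from a truth equation set, questionnaire
  exclusion flags — so every stage is testable without any real data.

## Worked example

Score a 28.6-year-old, 174 cm man's spirometry against the packaged
equations (`examples/01_zscores_and_lln.py`):

```python
from spirolms import (SpiroRecord, Subject, lln_for, load_ise,
                      percent_predicted, predict_median, zscore_for)

ise = load_ise("male")
subject = Subject(sex="male", age=28.57, height=174.0)
record = SpiroRecord(sex="male", age=28.57, height=174.0,
                     fev1=4.10, fvc=4.64, fev1_fvc=4.10/4.64, fef2575=4.50)
print(predict_median(ise, subject, "fvc"), zscore_for(ise, record, "fvc"))
```

prints the table

```
index      measured   median   %pred      z     LLN
fev1          4.100    4.081   100.5   0.04   3.467
fvc           4.640    4.680    99.1  -0.07   3.965
fev1_fvc      0.884    0.859   102.8   0.48   0.786
fef2575       4.500    4.482   100.4   0.02   3.557
```

Reading it: the man's FVC of 4.64 L sits at 99.1% of the predicted
median 4.68 L, z = −0.07 — a hair below the typical healthy value and
far above the LLN of 3.97 L (z = −1.645), so entirely normal. The same
subject's FEV1/FVC of 0.884 is half a standard deviation above the
reference median 0.859.

The other examples walk through cohort simulation and eligibility
filtering (`02`), refitting with SBC model selection (`03`), the
suitability report and equation-set ranking (`04`), and centile
curves/worm-plot data (`05`). Each prints the numbers it computes and a
line on what they mean.

## Layout

```
src/spirolms/
  distributions.py   BCCG/BCPE z-scores, quantiles, densities, LLN
  equations.py       equation-set types, JSON schema, packaged ISE
  cohort.py          synthetic cohorts, eligibility filter, CSV I/O
  gamlss.py          penalized backfitting, SBC selection, diagnostics
  validation.py      z-summaries, suitability, set ranking, rank tests
  cli.py             thin command-line pipeline over the library
docs/methods.md      modelling assumptions, numerics, limitations
examples/            one narrative script per capability
tests/               pytest suite (unit, property and acceptance tests)
```
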
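# Methods

This note records the models behind `spirolms`, the numerical choices,
what the synthetic-data generator does and does not emulate, and the
known limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Reference distributions

A healthy spirometric index *y* > 0 for a subject of a given sex, age
*a* (years) and height *h* (cm) is modelled as BCCG(μ, σ, ν) or
BCPE(μ, σ, ν, τ):

* μ > 0 — the median, in index units (L, L/s, or a fraction for
  FEV1/FVC);
* σ > 0 — approximately the coefficient of variation;
* ν — the Box-Cox skewness power (ν = 1 symmetric on the raw scale,
  ν < 1 right skew, ν → 0 the lognormal limit);
* τ > 0 — BCPE only: power-exponential kurtosis (τ = 2 normal, τ < 2
  heavier tails, τ > 2 lighter).

The z-score is `z = ((y/μ)^ν − 1)/(νσ)` (lognormal limit used when
|ν| < 1e-5), and for BCPE the transformed value is mapped through the
standardized power-exponential CDF (incomplete-gamma form, scale
`c² = 2^(−2/τ)Γ(1/τ)/Γ(3/τ)`) and then through Φ⁻¹. Quantiles invert
the chain; the lower limit of normal defaults to the 5th centile, with
the normal quantile at double precision (−1.6448536270), not a tabled
approximation.

**Truncation.** The Box-Cox transform formally truncates the reference
distribution (the constraint *y* > 0 leaves normal mass beyond
|z| = 1/(σ|ν|) unreachable). Following universal LMS practice this mass
is ignored everywhere. `boxcox_truncation_mass` computes it exactly;
scanned over ages 18–70 at the sex median heights, the packaged
equation sets peak at ≈ 2.7 × 10⁻⁴ (male FEF25–75 at age 18, where
σ = 0.153 and ν = −1.89) and the test suite asserts < 10⁻³. The
quadrature oracle in the tests restricts random parameter draws to
truncation mass < 10⁻⁹ so that the closed form and the integrated
density describe the same distribution to well inside the 10⁻⁷
comparison tolerance.

## Equation sets

Each distribution parameter of each index is a link-scale linear model

```
g(θ) = β₀ + β_h·ln(height) + β_a·ln(age) + s(age)
```

with g identity or log, and *s* an optional smooth age contribution
stored as a knot table (natural-cubic interpolation between knots,
clamped to the end values outside — extrapolating a smooth beyond the
observed age range is never justified). Logarithms are natural and
height is in centimetres; this convention is forced by internal
consistency — the packaged male FVC model evaluated at the median
demographics gives 4.68 L against a 4.64 L cohort median, whereas
base-10 logs or metre heights give absurd values. The packaged sets
reproduce their published coefficients digit for digit; a publication
ambiguity in the male FEV1/FVC mean row (a stray parenthesis) was
resolved by the same median-consistency check (the negative ln(age)
sign gives 0.859 against the 0.86 cohort median; the positive sign
gives 0.907).

Families follow the published parameter lists: BCPE only where a τ row
exists (female FEF25–75), BCCG elsewhere. The published models declare
`Mspline`/`Sspline` age terms on six of the eight indices without
publishing the spline shapes; the packaged files therefore carry empty
spline tables and require the explicit `acknowledge_missing_splines`
flag before they evaluate. Refitting on cohort data exports fitted
smooths onto integer-year knot tables, populating the same schema.
FEV1/FVC is stored as a fraction; readers divide values above 1.5 by
100 (published tables mix the two conventions). Ages outside 18–70
evaluate with a warning rather than an error, mirroring
reference-equation practice.

## Synthetic cohorts

The generator emulates the derivation-study population:

* **Sexes:** deterministic counts at the requested female fraction
  (default 0.331), shuffled.
* **Ages:** shifted log-normal, `age = 18 + LN(m, s)` truncated to
  [18, 70] by rejection; (m, s) calibrated to the reported medians and
  quartiles — males m = ln(10.57), s = 1.16 (median 28.6, Q1–Q3
  ≈ 22.7–40.7); females m = ln(16.79), s = 1.10 (median 34.8). Any
  right-skewed family matching the quartiles would do; the choice is
  recorded in the cohort metadata.
* **Heights:** normal truncated to the reported ranges; males
  N(174, 5.93²) on [155, 193], females N(157, 5.19²) on [154, 176],
  SDs from the reported IQRs (IQR/1.349).
* **Outcomes:** FVC, FEV1/FVC and FEF25–75 are drawn from the truth
  equation set's family at each subject's own (μ, σ, ν[, τ]); FEV1 is
  then *derived* as ratio × FVC so the physical constraint FEV1 ≤ FVC
  always holds. The (FVC, ratio) normal deviates are correlated at
  ρ = −0.4 — larger lungs empty proportionally slower — which keeps the
  derived FEV1's dispersion near its own model's σ. Draws are clipped
  at |z| ≤ 4 (and at 99% of the Box-Cox support bound where tighter): a
  screened healthy cohort contains no 4-sigma outliers, and the moment
  distortion is O(10⁻⁴). Ratio draws are capped at 1.0.

Consequences worth knowing. The three directly-drawn indices have
exactly calibrated in-sample z-scores (the tests assert |mean| < 0.05,
|SD − 1| < 0.05 at n = 10⁴). The derived FEV1 does **not**: the
packaged FEV1, FVC and ratio models are not mutually consistent (at the
male median demographics μ_FEV1 = 4.081 while μ_ratio·μ_FVC = 4.022),
so FEV1 z-scores against the FEV1 model carry a small negative offset
and mildly inflated SD — well inside the |mean z| < 0.5 suitability
band, and exactly the kind of cross-equation friction real equation
sets exhibit. The female ratio cap at 1.0 contributes a shift of about
−0.03 z. The generator does not simulate device measurement error
(±3% volume accuracy would add noise far below σ ≈ 10–15%), biological
covariates beyond sex/age/height, or the derivation study's exclusion
breakdown (flag prevalences are free parameters, default 0). Passing
tests on these cohorts therefore demonstrate internal consistency of
the pipeline, not field performance on real Iraqi data.

**Eligibility filter.** A record is kept iff age ≥ 18 and every
questionnaire flag (current smoker, lives with a smoker, former smoker,
chronic disease, pregnant, recent surgery/acute symptoms) is false;
exclusion reasons follow that listing order deterministically. The
phase split draws a validation sample of the requested size with at
least the per-sex minimum, stratified, and errors when impossible.

## Fitting

`fit_gamlss` is classical Rigby–Stasinopoulos backfitting. Per outer
cycle, each distribution parameter's linear predictor η is updated by
penalized weighted least squares with working response `η + u/w`, where
`u = ∂ℓ/∂η` and `w = −∂²ℓ/∂η²` come from central finite differences of
the exact per-observation log-likelihood (step 10⁻³·(1 + |η|); where
the numerical second derivative is not usably negative the squared
score replaces it — the standard quasi-Newton fallback; weights clipped
to [10⁻⁸, 10⁸]). Each update is step-halved (up to 10 times) against
the penalized deviance and reverted if no improvement is found.
Convergence: outer-loop penalized-deviance change < 10⁻⁶, at most 200
cycles; exhausting the budget returns a result flagged non-converged,
never a silent one. Spline-free fits are finished with a BFGS polish of
the exact likelihood. Records are sorted into a canonical (age, height,
value) order before fitting, making results bit-exactly invariant to
input shuffling. Initialization: μ by OLS on the link scale, σ from the
log-residual SD, ν = 1, τ = 2.

**Smooths.** `spline(age)` terms (allowed on μ and σ only) use a cubic
B-spline basis with 20 equally spaced interior knots over the observed
age range and a second-order difference penalty. The basis is
orthogonalized against the parameter's parametric columns so the
exported intercept/slope coefficients stay identifiable; the penalty is
kept on the original basis coefficients (a mild approximation). The
penalty strength is chosen each cycle by bisection so the parameter's
effective df — the trace of its smoother — hits a fixed target
(parametric columns + `spline_df`, default 3 extra df); a
penalty-optimized (e.g. local-ML) λ is a possible extension, but fixed
df keeps SBC comparisons across candidates interpretable. Fitted
smooths are exported by sampling onto integer-year knots.

**Selection.** Candidates are ranked by SBC; any candidate within
Δ_SBC = 2.0 of the best (the conventional "not worth more than a bare
mention" evidence band) with strictly fewer total df displaces it, and
a residual-moment screen (|mean| < 0.1, |var − 1| < 0.15) can veto a
winner. The default menu crosses {BCCG, BCPE} × {no spline, μ spline,
μ+σ splines} × {ν constant, ν ~ ln(age)} × (BCPE: τ constant,
τ ~ ln(age)), with μ always on ln(height) + ln(age) — 18 candidates
spanning every form appearing in the packaged sets.

**Identifiability caveat.** Adult cohorts have height CVs of only ~3%,
so ln(height) is nearly constant and the μ intercept and height slope
are heavily collinear: at n = 5000 their sampling SDs are ≈ 0.35 and
≈ 0.07 respectively, while ln(age) slopes, σ and ν are tightly
determined. Individual intercept/height coefficients from a refit
should be read jointly (the fitted median surface is accurate to ~1%);
comparisons between equation sets should be made through predictions,
not through single coefficients.

## Diagnostics

Quantile residuals are exactly the z-scores under the fitted model (no
randomization needed for continuous data); under correct specification
they are standard normal, which the suite checks by KS test across
seeded replicates. Worm plots bin records by age quantiles (equal
counts ± 1) and plot, per bin, sorted residuals against normal order
statistics Φ⁻¹((i − ½)/m), reporting the deviation. The diagnostic
reads the worm's *centering*: per-bin mean deviation near zero. The
pointwise deviations of the extreme order statistics are intrinsically
noisy even for perfectly normal data (their null max runs ~0.6 at
m = 1000), so bands should only ever be applied to the central region
or to the bin means — the tests assert per-bin means within ±0.15.
Centile curves fix height (default: the sex median) and sweep age; they
cannot cross, being quantiles of one distribution per age.

## Validation statistics

Summaries report mean (SD) and median (Q1–Q3) of z, plus median
(Q1–Q3) of predicted value and percent predicted, per index and sex.
Quantiles use linear interpolation (numpy default, type 7) — reporting
conventions differ across statistics packages and this one is fixed and
documented. Suitability is strict: |mean z| < 0.5 passes, 0.5 exactly
fails. Set comparison ranks by |mean z| with |SD − 1| as tie-break;
negative mean z means the set overestimates. Mann–Whitney U uses
midranks; the two-sided p is exact by enumerating all C(n, n_a) rank
assignments when the smaller group has ≤ 8 observations and the
enumeration stays under 5 × 10⁵ combinations, otherwise the normal
approximation with tie-corrected variance and a 0.5 continuity
correction toward the mean. KS normality wraps the one-sample test
against the standard normal with the asymptotic p-value.

## Problem sizes

The test suite and acceptance script use the sizes their properties
need and nothing more: n = 10⁴ for generator calibration (Monte-Carlo
error ~0.01 z), n = 5000 per sex for parameter recovery, 20 seeded
replicates at n = 1000 for selection consistency and suitability rates,
and exhaustive enumeration up to 6 per group for the rank test. A full
fit at n = 5000 takes well under a second; the whole acceptance script
runs in seconds.

## Known limitations

* The packaged sets evaluate with zero spline contribution until
  refitted on data; where the published models declared splines, the
  packaged predictions are the parametric backbone only (the
  median-demographics screen shows this backbone sits within 5% of the
  cohort medians).
* BCPE τ is weakly identified when large (light tails look alike);
  refits recover the τ model's effect on the likelihood but not
  necessarily its coefficients.
* The suitability rule judges the population mean only; a set can pass
  it while mis-shaping the tails — that is what the SD, centile and
  worm diagnostics are for.
* The fitter targets fixed smoothing df rather than estimating λ by
  REML/ML; model complexity is explored through the menu instead.
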
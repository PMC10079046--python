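# Methods

`submort` estimates province-level under-5 mortality (U5MR, the probability
of dying before exact age 5 per 1,000 live births) and neonatal mortality
(NMR, deaths in the first completed month per 1,000 live births) from
heterogeneous, incomplete data sources, and projects NMR forward under
annual-rate-of-reduction scenarios against the SDG 3.2 threshold of 12
neonatal deaths per 1,000 live births. This note documents the statistical
model, the defaults, the synthetic-data generator used for validation, and
the numerical choices.

## Observation model

Every input is reduced to a `MortalityObservation`: a rate per 1,000 live
births at a (province, reference year), with a design variance on the log
scale and a source label. Three estimator families produce observations:

* **Death registration (DRS).** Registered death counts over live births.
  Registration captures only a fraction *c* (the completeness) of true
  deaths, so on the log scale the observed rate is the latent log rate plus
  log *c*.
* **Complete birth histories (CBH).** Per-child records of birth date and
  survival. The direct estimator divides weighted under-5 deaths in a
  calendar year by weighted person-years of under-5 exposure and converts
  the rate to a 5q0-type probability via the constant-hazard identity
  5q0 = 1 − exp(−5m). This identity is exact only for a flat hazard; with
  the front-loaded age pattern of child mortality it overstates 5q0 by about
  1% at these mortality levels, which is far below the sampling noise of any
  realistic survey. When estimates are produced for several years at once,
  years whose cohorts are not fully observed (births before the recall
  window would have contributed exposure) are dropped: keeping them retains
  only the youngest, highest-hazard children and biases the rate upward.
* **Summary birth histories (SBH).** Children ever born (CEB) and children
  dead (CD) per five-year maternal age group. The maternal-age-cohort (MAC)
  route converts each group's CD/CEB into a 5q0 by a multiplier and locates
  it in time by a cohort offset; the maternal-age-period (MAP) route pools
  groups into pre-survey period buckets (0–4, 5–9, 10–14 years). The
  multipliers and offsets are a pluggable `CoefficientSet`: a fixed
  classical (Brass/Trussell-style) default, an identity set for algebraic
  tests, and a `calibrated()` builder that derives the coefficients for a
  stated fertility schedule by direct exposure simulation against a
  reference survival curve — the standard way such coefficients are derived
  from model schedules. The reference curve's neonatal share defaults to
  0.74, consistent with the package's default NMR–U5MR relation at typical
  mortality levels.

Before any source enters the pipeline it passes the data-quality gate:
reject when key-variable missingness exceeds a cutoff (default 0.10,
configurable within 0.05–0.10) or when the boys-to-girls sex ratio falls
outside the inclusive band [1.00, 1.06].

Two ingestion conventions matter for unbiasedness and are applied uniformly:

* **Log-scale mean correction.** A count-based rate estimate is unbiased in
  levels but biased low on the log scale (Jensen). Models with Gaussian
  likelihoods on log rates therefore add the exact correction
  log λ − E[log max(X, ½)] for X ~ Poisson(λ), with λ taken as the
  reciprocal of the design variance. The exact form matters: the common
  σ²/2 rule overcorrects badly below about five expected deaths.
* **Exogenous working variances.** Design variances are computed from a
  fixed working rate (5q0 = 0.02), never from the cell's own death count: a
  variance estimated from the same count as the estimate makes
  precision weights positively correlated with the estimates and biases any
  weighted fit upward. Cells whose working expected deaths fall below two
  are dropped altogether — their log-scale values are count artifacts.

## Stage model 1: Gaussian-process regression

The mean function is a linear mixed model on log rates with fixed covariate
effects (wealth index, years of schooling, urbanization in the synthetic
data) and crossed random intercepts for province and calendar year, fit by
REML (statsmodels `MixedLM` with variance components; falls back to
province-only intercepts on small panels and to plain least squares when
the variances degenerate). The year intercepts are an estimation nuisance:
a shared temporal shock projects onto the covariates' time trends and would
otherwise both bias the slopes and deflate their standard errors. They are
excluded from the predicted mean — temporal structure is the downstream
smoother's job. In the pipeline the mean is fit on the survey sources only,
so under-registration cannot drag the mean level.

Deviations from the mean follow a zero-mean Gaussian process on the
province × year grid with a separable covariance: Matérn(ν, ℓ) in time
(default ν = 1.5, prior median ℓ = 5 years) times either a graph-diffusion
kernel `expm(−ρL)` on the adjacency Laplacian (default) or an exchangeable
correlation. The amplitude carries a log-normal prior (median half the
`amplitude_sd` setting, log-sd 1): a zero-amplitude GP is degenerate — the
posterior collapses onto the mean function with no spread — so the prior
keeps the field scale bounded away from zero.

Observation noise is the design variance plus a source-specific
non-sampling variance (half-normal priors). Two further per-source terms
capture systematic error: the registration completeness *c* enters as an
additive log *c* offset with a Beta prior (default Beta(9, 3), a stand-in
for registration above half and below full coverage; the study data this
emulates report only ">50% incompleteness" before 2005), and each indirect
source carries a mean-offset parameter with a zero-centred normal prior
(default sd 0.1) — the mean component of non-sampling error, which for
cohort-based indirect estimates is genuinely nonzero under fluctuating
mortality (a cohort ratio reflects the arithmetic mean of mortality over
its birth-year mix).

Because the likelihood is normal on log rates, the latent field is
conditionally Gaussian given the hyperparameters. Default inference
maximises the penalized marginal likelihood over the hyperparameters
(L-BFGS-B in transformed space), then propagates hyperparameter uncertainty
with a Laplace approximation: Gaussian draws of the hyperparameters around
the optimum (finite-difference Hessian, curvature floored at 1 in
transformed space), one exact conditional draw of the field per
hyperparameter draw. Propagating the completeness uncertainty is what gives
the posterior honest width in the level direction — a point estimate of *c*
understates every interval by the same shift. An MCMC route (ensemble
sampler over the hyperparameters, field still analytically marginalised) is
available; R-hat is computed across walkers and a value above 1.05 logs a
warning rather than failing silently.

## Stage model 2: spatiotemporal smoothing

log rate = intercept + linear time trend + BYM2 spatial effect + RW2
temporal effect + type-I (independent) province-year interaction, with the
normal likelihood on log rates and a small nugget. The spatial effect uses
the scaled BYM2 parameterisation: total spatial sd σs and mixing φ between
a scaled intrinsic CAR (ICAR) structured part and an unstructured iid part.
The improper ICAR and RW2 priors are represented on the eigenbasis of their
precisions restricted to the proper subspace, scaled so a unit variance
parameter gives unit geometric-mean marginal variance. Consequences: the
structured spatial effect sums to zero and the RW2 effect is orthogonal to
constants and linear trends by construction (the identifiability
constraints hold to machine precision in every draw), and the RW2 null
space — linear time trends go unpenalized — is carried by the explicit
intercept and trend fixed effects, so a linear-in-time truth is reproduced
exactly.

Hyperparameters (σs, φ, σt, σu, nugget) get half-normal priors (φ uniform)
and the same optimise-then-Laplace treatment; all Gaussian effects are
drawn exactly from their joint conditional. This model has no completeness
parameter: the pipeline divides registration observations by the GP stage's
completeness estimate before fitting and propagates that estimate's
uncertainty as a common log-scale level shift per draw (the adjustment
moves every registration observation together, so its error is a level
error, not independent noise). With one observation per cell the
interaction and nugget variances are identified only through their sum;
both are reported.

## Model averaging

20% of registration observations and 20% of the remaining sources (the two
strata) are held out at random. Each stage model is scored on the held-out
points by log-scale RMSE (registration test values completeness-corrected
with the model's own estimate) and by the share of points inside its
central 95% interval. Models are ranked by RMSE with the distance of
coverage from 0.95 as tie-break (a rank-sum combination of both metrics is
available), and weighted by a monotonically declining function of rank —
default linear in reverse rank (two models: 2/3 and 1/3), exponential decay
as an alternative. The combined surface samples each output draw from model
k with probability equal to its weight; mixture quantiles are validated
against a brute-force pooled-draw oracle in the tests.

## Neonatal mortality

Pooled over province-years, log NMR is quadratic in log U5MR; province-year
effects δ let provinces sit above or below the curve. The quadratic is fit
by least squares of corrected log NMR observations on the posterior-median
log U5MR (registration completeness proxied by the under-5 estimate — no
independent source exists for neonatal completeness); the residuals are
smoothed by both stage models (as pseudo-observations whose log value is
the residual) and combined by the same holdout/rank-weight machinery. NMR
draws are assembled over a thinned set of U5MR draws (default 100) with
coefficient draws from the least-squares sampling distribution, so both
uncertainty sources propagate; every draw is truncated at its paired U5MR
draw — a neonatal death is an under-5 death, so NMR ≤ U5MR holds draw-wise
by construction. Note the quadratic's two regressors are strongly collinear
over the observed mortality range, so individual coefficient uncertainties
are large even when the fitted curve is tight; recovery checks work on the
coefficient-SD scale for exactly that reason.

## Projection

ARR(t1→t2) = ln(rate(t1)/rate(t2))/(t2−t1), positive for decline. Five
scenarios set each province's 2018–2030 ARR from its base-2017 rate and its
observed 2010–2017 ARR: hold constant; keep own trend; adopt the best ARR
in the province's region; decline exactly to the SDG threshold by 2030
(provinces already at or below the threshold keep their own trend, which
keeps the scenario at least as good as own-trend); adopt the mean ARR of a
designated set of high-income provinces (a required input — no canonical
set exists). Death counts are rate × live births at full precision,
rounded half-up only in reported integers; national rates are
live-birth-weighted aggregates; a province meets SDG 3.2 iff its 2030 NMR
is at or below 12 (counts of provinces *above* target use strict
inequality, which is what makes provinces at 12.1 count as short of the
target while exact-threshold values do not).

## Synthetic data

The generator draws one latent truth and the sources that observe it:

    log U5MR[p,t] = x[p,t]·β + φ_p + ψ_t + ε_{p,t}
    log NMR[p,t]  = β0 + β1·log U5MR + β2·log U5MR² + δ_{p,t},  NMR ≤ U5MR

with φ an ICAR field on a grid/ring/random-planar province graph, ψ a
constrained RW2, ε and δ iid. Default fixture: 8 provinces in 2 regions,
years 2005–2017, seed 20170101; β = (3.0, −0.30, −0.20, −0.15) on
standardized covariates (baseline ≈ 20 per 1,000), component sds
(0.15, 0.10, 0.05), quadratic (−0.40, 1.05, −0.005) giving a neonatal share
near 75%, 20,000 live births per province-year. Registration completeness
is drawn uniformly on (0.6, 0.95) per province-year (a constant-over-time
option exists); the range is a stand-in — the emulated registry documents
only that completeness exceeded one half in its worst years. Survey scales
follow the study design the generator emulates: the complete-birth-history
survey uses 3,500 mothers per province (a national survey of ~114,000
households spread over 31 provinces) and the summary-birth-history survey
400 mothers per age group (census samples are larger still). The SBH
fertility schedule is a fixed parity vector (0.25…3.5 by age group), since
only the CEB/CD → mortality mapping is under test.

What the generator does **not** emulate: age-pattern model life tables
(mortality is a two-piece constant hazard: the neonatal month, then months
1–59), fertility differentials by province or time, migration,
household-level clustering and design effects in surveys, and correlation
of completeness with mortality. Passing the synthetic recovery tests
therefore shows the estimation machinery is correct and calibrated under
the stated generative assumptions, not that real registries or surveys
satisfy those assumptions.

## Numerical choices and conventions

* Rates live in (0, 1000) per 1,000; all modelling is on natural logs.
* Years are calendar integers on the model grid; fractional reference
  years map to the nearest grid year, observations further than a year
  outside the grid are dropped with a warning.
* Transformed hyperparameters are box-bounded (log scale ±12, logits ±8)
  to keep the marginal likelihood finite during optimisation.
* Conditional covariance Cholesky factors get an escalating jitter
  (starting at 1e-10 of the mean diagonal) before failure is reported.
* Zero-death cells use a half-death continuity correction; a cohort with
  zero children dead yields a zero point estimate, which is floored at
  half a death among the pooled CEB only when converted to a log-scale
  observation.
* Ranks order provinces by rate (rank 1 = lowest); ties break by label.
* Seeds: every public entry point takes a seed; the pipeline derives
  per-stage seeds from the global seed via `SeedSequence`, making the full
  run bit-reproducible (checked by hashing all outputs).

## Validation summary

The test suite checks, among others: the CAR full-conditional
neighbour-average identity against the partitioned joint precision; the
RW2 lag-1 autocorrelation of generated temporal effects against a direct
double-cumulative-sum simulation of the prior; the spatiotemporal
posterior mode against a brute-force penalized least-squares solve;
mixture quantiles against pooled draws; hand-computed RMSE and rank
weights; and, as the headline calibration experiment, 200 independent
replicates of the full multi-source estimation on the default fixture at
reduced draw counts (100), in which the combined surface's central 95%
intervals are required to cover at least 90% of true province-year rates —
the gap to the nominal 95% is the price of the Laplace approximation, the
shared-completeness approximation, and rank-weight model averaging. The
replicate counts and draw counts are chosen so the full suite runs in
minutes on a single core.
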
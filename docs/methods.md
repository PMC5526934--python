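# Methods

This note documents the statistical machinery, the defaults and the
numerical choices of `caribou_pva`, and what the synthetic-data tests do
and do not establish about real monitoring data.

## Survival estimation

Annual adult-female survival is the staggered-entry Kaplan–Meier estimator
computed per population and biological year (1 April – 31 March). Raw
collar histories are first cut at year boundaries; an animal alive across a
boundary re-enters on 1 April. Within a year, the estimate is the product
over distinct death times *t* of (1 − d_t / n_t), with the risk set
{entry < t ≤ exit}. Conventions where the data leave room: tied deaths form
a single step; deaths are processed before censorings tied at the same
date; animals contribute risk only after their individual entry date.
Population-years with fewer than 6 distinct monitored females are dropped
and logged. The weight attached to each estimate is the number of distinct
females monitored at any point in that year, matching the reported 6–22
collared range.

Verification is dual-route: a day-by-day brute-force risk-set product and
the left-truncated Kaplan–Meier implementation in `lifelines` both
reproduce the estimates on hundreds of random staggered/censored instances,
and with common entry and no censoring the estimator reduces exactly to the
binomial surviving fraction.

## Recruitment observations

Aerial-survey counts give calves, adult females, adult males and
unclassified adults. Unclassified adults are apportioned to females by the
survey's own sexed fraction F/(F+M) when unclassified adults make up less
than 10% of all adults, and by a regional 65% female assumption otherwise
(the boundary case uses the assumption, reading the rule strictly as
"fewer than 10%"). The 65% value is consistent with the pooled sexed
classification of 699 adults (453 females). Surveys with fewer than 50
individuals (calves plus all adults, reading "individuals observed" as all
animals) are dropped and logged. The recruitment ratio R = calves /
corrected females carries the corrected female count as its weight, and the
disturbance covariate is lagged one year: calves counted in late winter
reflect the previous year's exposure.

## Weighted binomial mixed models

Both vital rates are modelled with a logit link and a single
population-level random intercept:

    logit p_ij = x_ij' β + u_j,  u_j ~ N(0, σ²)

Survival responses are Kaplan–Meier proportions, not integer counts, so the
observation log-likelihood is the quasi-binomial form
w·[y·log p + (1−y)·log(1−p)]; with integer successes/trials this is the
exact binomial likelihood up to a constant. Recruitment supports both the
ratio-with-weights form (default) and integer trials at the rounded
corrected female count; the two agree closely on simulated data.

The marginal likelihood integrates u out with adaptive Gauss–Hermite
quadrature (default 15 nodes) centred and scaled at each group's posterior
mode (one node = Laplace). The optimizer is L-BFGS-B over (β, σ) with σ
bounded at zero, followed by Newton polishing of β on the
quadrature-approximated score, so that when σ̂ = 0 the estimates match a
plain weighted GLM to machine precision. Fits agree with R's
`lme4::glmer` (nAGQ = 15) to ~1e-5 on test data. The coefficient
covariance is the inverse observed information at the optimum (numerical
central-difference Hessian); when σ̂ sits at the boundary the Hessian is
taken over β alone. Degenerate inputs are rejected explicitly:
rank-deficient weighted designs (e.g. a single population, which confounds
P with the intercept), boundary responses (all-zero calves → separation),
non-positive weights.

Confidence intervals use the parametric bootstrap: responses are resimulated
from the fitted model (fresh population intercepts, binomial draws at the
rounded weights), refit with warm starts, and the 2.5/97.5 percentile
bounds taken; more than 10% failed refits aborts with an error. The
bootstrap (not the Hessian) is the authoritative interval method. A
simulation with 200 replicated monitoring programs shows interval coverage
of the generating disturbance coefficient near the nominal 95% (the check
accepts ≥88% to allow for the small-resample undercoverage of percentile
intervals at 99 resamples).

## Growth rate and thresholds

λ_f = S_f / (1 − R_f) with R_f = (R/2)/(1+R/2) simplifies to
λ_f = S_f·(1 + R/2). Predictions use fixed effects only (random intercepts
at zero), making the threshold machinery population-generic; a
population-specific intercept would shift individual curves. With both
disturbance coefficients negative λ_f is strictly decreasing in D, and the
λ_f = 1 threshold is solved by bisection to an interval width of ~3e-14
(tolerance far below the 1e-6 target); a dense grid scan of the same
definition ("largest D with λ_f ≥ 1") agrees within 2e-4.

Uncertainty propagation draws coefficient vectors from N(β̂, V̂) for each
model independently (the models are fitted separately; no cross-covariance
exists), solves each draw's threshold (bisection for monotone draws, grid
scan for the rare draws with a positive disturbance coefficient), and takes
the 5th percentile: equivalently, the largest D at which ≥95% of draws give
λ_f ≥ 1 — the two readings coincide under monotonicity and are tested
against each other on shared draws. The default 10,000 draws give
seed-to-seed stability within 0.01 of D. A bootstrap-refit backend for the
draws is deliberately not provided at the default scale (10,000 refits per
grid point); the normal approximation to the sampling distribution is the
implemented reading.

## Succession models

Stand height and canopy cover are ordinary least squares on
{age, age², P, age×P}; the interaction lets the effect of productivity vary
with stand age. Raw canopy cover is divided by the treed fraction of the
pixel, and raw deciduous fraction by the vegetated fraction, before
modelling; treeless or unvegetated pixels are removed and logged, and
corrected values above 1 are capped. The deciduous fraction uses a
penalized cubic B-spline smooth of age (~10 basis functions) plus linear P
and age×P terms, with the penalty weight chosen by generalized
cross-validation over a log-spaced grid; predictions are clamped to the
training age span, where the basis is defined. A constant response
short-circuits to a constant fit. On synthetic pixels the fitted deciduous
peak lands within ±3 years of the generating peak at age 20.

## Synthetic-data generator

The generator reproduces the study conditions of the six-population,
ten-year monitoring program: P uniform on [0.04, 0.85]; non-decreasing
yearly disturbance trajectories inside [0.22, 0.78] (start uniform on
[0.22, 0.70], yearly increments uniform on [0, 0.02] — disturbance
accumulates and nothing ages out within the simulated horizon); ~15
collared females per population-year (published range 6–22) with lost
collars replaced the next year; 150 observed females per survey (published
range 50–252); the published logit-scale coefficients as generating truth;
population random-intercept SD 0.2; per-year censoring probability 0.1
(plausible collar loss; not a published value); 8% expected unclassified
adults per survey, chosen so realized fractions straddle the 10% correction
boundary; 65% true female fraction. Death and censoring compete within a
year — whichever simulated date is earlier wins — and death dates follow a
constant within-year hazard calibrated to the annual survival probability
(the models only use annual probabilities, so the within-year shape is
inconsequential). Half of new collars deploy on 1 April, half uniformly
through September. Random intercepts for survival and recruitment are
independent by default, matching separately fitted models. Every stream is
keyed to one integer seed; identical configurations are byte-identical.

What the generator does *not* emulate: spatial structure and movement,
density dependence, temporal autocorrelation in vital rates beyond the
shared intercept, detection error in surveys (the survey method's ~85%
detection is not corrected for in the models either), cause-specific
mortality, and multi-year collar gaps. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated generating
model, not robustness of the original field inference to these features.

## Problem sizes and seeds

The recovery experiment runs at 60 populations × 10 years (600
population-year survival estimates, 540 surveys), large enough that each
coefficient's Monte-Carlo SE is a fraction of the published standard
errors while a full run stays under a second; across seeds the recovery is
unbiased with Monte-Carlo spread matching the model-based SEs, so a
single-seed estimate is expected within two SEs of truth. The coverage
simulation uses 200 replicates of a deliberately small 6-population design
with 99 bootstrap resamples each. Stochastic tests fix seed 20170725.

## Known limitations

- The published survival predictions for the extreme ranges (0.81/0.91)
  are not recoverable from the published fixed effects under a logit link
  (which give 0.84/0.92); they likely include population intercepts or
  unrounded coefficients, and are not used as checks here.
- Published models carry only standard errors, so their assembled
  covariance is diagonal; confidence thresholds built from them ignore
  coefficient correlations and are conservative.
- Per-population withstand levels for the original six ranges need the four
  unpublished population productivity values and are out of scope.
- The λ_f expression is a two-stage female-segment approximation, not an
  age-structured projection; it assumes the calf/female ratio translates
  directly into recruitment of yearling females.
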
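# Methods

## The estimation problem

National family planning indicators must be estimated from survey records
that are sparse (a handful of surveys per country over five decades),
heterogeneous (different survey programmes with different biases and
precisions), and temporally diffuse (fieldwork spans one or two years).
The package treats this as a Bayesian hierarchical state-space problem:
a structured latent process per country, a measurement model per survey
row, and hierarchical sharing of curve parameters across the geographic
hierarchy.

## Latent process

Annual integer grid, 1970–2030 by default (`ModelConfig.year_start/end`).
For country *c* with grid years *t*:

* **Total use.** η_{c,t} (logit total prevalence) starts on the expected
  logistic curve Λ_c at the first grid year and evolves as
  η_{c,t+1} = η_{c,t} + [logit Λ_c(t+1) − logit Λ_c(t)] + δ_{c,t},
  with δ a stationary AR(1)(ρ_η, τ_η) series: the *rate of change*
  deviates persistently from the expected rate. Beyond the last
  observation the AR prior reverts the realised rate toward the expected
  curve, so projections are informed by both the recent pace and the
  historical transition shape. There is no level distortion for total
  use; the level at the (data-free) grid start is tied to the curve.
* **Modern share.** A deterministic logistic curve in time with its own
  asymptote, rate and midpoint; modern use = total × share. The share
  has no distortion series, so the split between modern and traditional
  use evolves smoothly.
* **Unmet need.** Modelled among non-users: u_{c,t} = α_c + β η_{c,t} +
  ε_{c,t} with ε a stationary AR(1)(ρ_u, τ_u) *level* distortion, and
  unmet(any) = (1 − total) · expit(u). This construction keeps
  total + unmet ≤ 1 for every draw by design.

The seven transformed curve parameters per country — logit p̃, log ω, Ω,
logit r̃, log ψ, Ξ, α — are exchangeable within a subregion:
country ~ N(subregion, σ_country), subregion ~ N(region, σ_subregion),
region ~ N(world, σ_region), componentwise.

## Measurement model

Survey rows carry a proportion in (0,1), a source type, a reference
period, and optionally a proportion-scale sampling SE. On the logit scale
an observation informs the overlap-weighted average of its indicator over
the grid years intersecting its reference period (weights proportional to
fractional-year overlap with each [Y, Y+1)); a calendar-year survey
without months sits at mid-year, Y + 0.5. The error model is

    z ~ Normal( logit(period-average) + bias_source , v_sampling + sd_source² )

with `v_sampling = se² / (v(1−v))²` the delta-method image of the reported
SE at the reported value, `bias_DHS = 0` as reference, other biases given
N(0, 0.2²) priors, and half-normal(0.2) priors on the non-sampling SDs.
Missing SEs are imputed as the median reported SE of the same source type
and indicator, falling back to 0.015 (proportion scale). Service
statistics (EMU) enter through first differences of logit modern use with
a fixed variance per differenced point (default 0.005), so a constant
level offset of the service data cancels; series with fewer than two
points contribute nothing (logged).

## Priors (defaults, all overridable)

| parameter | prior | rationale |
|---|---|---|
| world mean of logit p̃ | N(0.5, 1²), p̃ kept in (0.1, 0.95) | broad; transition asymptotes seen in practice |
| world mean of log ω, log ψ | N(log 0.1, 0.5²) | decade-scale transitions |
| world mean of Ω, Ξ | N(2000, 10²) | observed transition midpoints |
| world mean of logit r̃ | N(0.5, 1²) | broad |
| world mean of α | N(0, 1²) | broad on unmet-among-non-users |
| hierarchy SDs | half-normal(0.5); half-normal(5 yr) for Ω, Ξ | unit-aware: a 0.5-year cross-country spread of midpoints would be dimensionally inconsistent with the world-level spread |
| ρ_η, ρ_u | Uniform(0, 0.95) | positive persistence, bounded away from a unit root |
| τ_η, τ_u | half-normal(0.1) | distortions are a perturbation, not the trend |
| β | N(0, 0.5²) | weak coupling of unmet need to prevalence |

## Posterior computation

The sampler is a block MCMC scheme (`fpem.inference`):

* **Country curve parameters** — univariate slice sampling of each of the
  seven components in *compensated coordinates*: while a component moves,
  the distortion series is translated so the latent increments are
  preserved (a unit-Jacobian bijection), so the conditional density is
  the hierarchical prior times the AR(1) prior of the implied distortions
  times a small residual likelihood term. This removes the funnel between
  "curve explains the data" and "distortions explain the data" that
  defeats naive Metropolis updates on this model.
* **Distortion series** — elliptical slice sampling with exact stationary
  AR(1) prior draws, which mixes independently of ρ and τ.
* **Hierarchy means** — conjugate normal draws (the world-level asymptote
  component by truncated normal); **hierarchy SDs, AR parameters, β,
  non-sampling SDs** — univariate slice sampling; **source biases** —
  conjugate normal.

Chains run sequentially from `numpy` Philox streams spawned from the seed,
so results are bit-for-bit reproducible for a given (data, config, seed).
The likelihood kernel is compiled with numba. Split-R-hat and effective
sample sizes (via arviz) are reported per scalar; `converged` means all
split-R-hat < 1.1. Non-convergence is reported and logged but draws are
returned — downstream counterfactual pipelines need partial results, and
the *trajectory-level* quantities mix far faster than weakly identified
raw curve parameters (asymptotes of countries far from saturation, e.g.,
are prior-dominated and may carry large R-hat without affecting indicator
summaries; assess convergence on the quantities you report).

Default sampling effort: 4 chains × (1000 warmup + 1000 draws) for
production use; tests and the acceptance script use 2 × (500 + 500) with
the 16-country scenario, which one CPU fits in about a minute.

## Derived indicators and reports

All derived quantities are computed per draw and then summarised (median,
2.5th/97.5th percentiles with linear interpolation between order
statistics): unmet need for modern methods = unmet(any) + traditional
use; demand satisfied = mCPR / (mCPR + unmet modern); users = mCPR ×
MWRA. The plug-in ratio applied to published medians reproduces the
printed demand-satisfied values to one decimal in the packaged tables,
but the identity is exact only draw-wise. Aggregation weights prevalences
by MWRA counts per draw and year (population counts treated as known);
user counts add exactly. Report tables round half-away-from-zero to one
decimal on the percentage scale.

The counterfactual analysis removes every observation whose period
*starts* strictly after the cutoff (an observation starting exactly at
the cutoff stays), refits, and evaluates each affected country at its
most recent observation year (latest period end, service statistics
included): the attainment probability is the fraction of counterfactual
draws at or above the full-data posterior median (the median is the
declared point summary). Groups split at ≤25% and ≥75%; "positive
progress" requires a positive median gap *and* attainment below 50%,
both strict. A 2-SD outlier screen against a projected trend is provided
(`flag_outliers`, strict inequality at exactly two SDs) for datasets with
suspect recent surveys.

## Synthetic data

The generator (`fpem.synthetic`) draws every truth from the model's own
priors — hierarchy, curve parameters, distortions, biases, non-sampling
SDs — and simulates surveys with the model's own measurement process, so
fitting generated data is a draw from a self-consistent Bayesian
experiment and posterior intervals should attain nominal coverage up to
Monte Carlo error. Specifics:

* Survey events per country are uniform on a configured range; each event
  yields total-use and modern-use rows and, with configured probability,
  an unmet-need row; reference periods last one year (probability 0.7) or
  two.
* Sampling error is binomial-realistic: an effective sample size per
  survey (uniform on 1500–8000 by default) gives logit-scale sampling
  variance 1/(n_eff·p(1−p)); the reported proportion-scale SE encodes
  exactly that design-based variance under the pipeline's delta-method
  convention, mirroring variance estimation from survey micro-data.
  (Encoding instead a plug-in SE from the noisy point estimate makes
  upward-noised observations of rare outcomes look spuriously precise
  and measurably biases recovery — an instructive failure mode the test
  suite guards against.) Non-DHS rows lose their SE with probability 0.5.
* EMU series get a country-level logit offset (SD 0.3) plus iid noise
  (SD 0.05); the model's first-difference likelihood treats differenced
  residuals as independent although they are MA(1) under the generator —
  a deliberate, minor misspecification retained because differencing is a
  bias-cancelling device, not a full error model.
* Scenario `tiny` is 3 countries (smoke tests); `small` is 2 regions × 2
  subregions × 4 countries = 16; `fp2020_like` is 68 countries with
  survey, unmet-need and service-statistic volumes proportioned to the
  observed multi-country database (~730 prevalence events, ~460
  unmet-need rows, ~85 EMU points in 13 countries).

What passing tests on this generator do **not** show about real data:
real surveys have design effects, non-ignorable timing, correlated
indicator errors within a survey, and biases that drift over time; the
generator draws none of these, so recovery results here bound what the
model can do when its assumptions hold, not how it behaves under real
misspecification.

## Numerical choices and edge cases

Logit curve values are computed via softplus to avoid underflow for
extreme parameters; proportion paths are clipped to [1e-14, 1−1e-14]
inside the likelihood so logits of weighted averages stay finite.
Observations at exactly 0 or 1 are rejected at parse time, as are
reversed reference periods and non-positive SEs; missing SEs are kept
missing, never zeroed. A degenerate (point) reference period takes the
single grid year containing it. Slice samplers cap bracket shrinkage at
100 evaluations and keep the current value in the pathological case.
Ties in attainment draws count toward attainment (draws ≥ estimate).

## Known limitations

* Raw curve parameters can remain weakly identified (high R-hat) in short
  runs even when indicator paths have converged; the reported `converged`
  flag is strict.
* The delta-method variance mapping is evaluated at the reported value;
  for very rare outcomes with *plug-in* (rather than design-based)
  reported SEs this overweights upward-noised observations.
* Population counts carry no uncertainty, matching the reporting
  convention for user numbers.
* All-women (rather than married/in-union) denominators, age structure,
  method mix and covariate effects are out of scope.
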
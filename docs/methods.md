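# Methods

## The estimation problem

Questionnaire sleep duration is ordinal: a respondent ticks one of a small
set of categories, and the categories differ between survey waves. Treating
a category as an exact value (e.g. "7.5" as 7.5 h) discards the known
coarseness and makes waves with different categories incomparable. The
package instead models a latent continuous sleep duration and treats each
response as the event that the latent duration fell in the category's
interval — interval censoring. The two open-ended categories are one-sided:
"6 h or less" is left censoring on (0, 6.25), "10 h or more" is right
censoring on [9.75, ∞).

### Response schemes and interval boundaries

Interior categories are read as "rounded to the nearest offered value" and
mapped to half-open intervals centred on the stated value, with the wave's
spacing as width: 1.0 h for the 1975 scheme (seven categories), 0.5 h for
the 1981/1990/2011 scheme (nine categories). The 1975 scheme's lowest
option, "less than 4 h", is mapped to (0, 4.5): the options list skips a
plain "4", and the open lowest category absorbs the gap so the scheme still
tiles (0, ∞) — this covers both the literal reading and the "4 h or less"
reading. Because every likelihood contribution is S(left) − S(right) of a
continuous model, the half-open boundary convention itself carries no
probability and is immaterial; it only matters for the deterministic
`discretize`/`map_response` round trip, which is tested exhaustively.
Schemes are serialisable to YAML so alternative boundary choices can be
evaluated without code changes.

## The regression model

Hazard of the latent duration ending ("waking") for subject *s* of pair *p*:

    h(t | x, u) = k t^(k-1) exp(beta0 + x'beta + u_p + u_ps)

- `k` (shape, dimensionless): controls the spread; at the calibrated
  reference mean 7.7 h and SD 0.9 h, k ≈ 10.3.
- `beta0`: log baseline hazard scale; with the above calibration ≈ −21.5.
  Only `-beta0/k` (a log time scale) is directly interpretable.
- `beta` (log hazard ratios): indicator contrasts for birth cohort
  (reference <1900), age group (reference 18–34) and gender (reference
  female). exp(beta) > 1 ⇒ the level has a higher hazard at every duration
  ⇒ stochastically shorter sleep. Mean duration is
  E[T] = Γ(1 + 1/k)·exp(−(beta0 + x'beta)/k), so higher hazard ⇒ lower
  mean, monotonically (tested).
- `sigma_pair`, `sigma_ind` (SDs of the random intercepts, log-hazard
  scale): capture twin-pair similarity and within-person stability across
  waves. The induced frailty exp(u) is log-normal. Defaults in the
  generator are 0.25 and 0.20 — chosen as plausible moderate intra-cluster
  correlations; they are free truth parameters of the simulation, not
  published estimates.

Age group and birth cohort are both included despite their partial
confounding with survey wave (age = wave − birth year); with four waves the
contrasts are identified, and the fitter errors only on exact rank
deficiency. Levels absent from (or constant in) the data are dropped with a
warning and their coefficients pinned at 0.

## Likelihood and integration

Each pair contributes

    L_p = ∫ φ(u_p; σ_p) ∏_{s∈p} [ ∫ φ(u; σ_i) ∏_{o∈s} {S(L_o|η) − S(R_o|η)} du ] du_p

with η = beta0 + x'beta + u_p + u. Both integrals use non-adaptive
Gauss–Hermite quadrature (default 25 nodes per level; 15 in the bulk
replicate harnesses — coefficient differences between 15 and 35 nodes are
below 1e-3 on cohort-sized data, which is tested). With σ_p = σ_i = 0 all
nodes collapse to u = 0 and the marginal likelihood equals the fixed-effects
interval-censored Weibull likelihood exactly (identity holds to 1e-10,
tested). Agreement with 200,000-draw Monte Carlo integration within 3 MC
standard errors is part of the acceptance suite.

Numerics: with a = L^k e^η and b = R^k e^η, log{S(L) − S(R)} =
−a + log1p(−e^{a−b}), which handles left censoring (a = 0), right censoring
(b = ∞) and near-cancellation uniformly. Exponents are clipped at 700 and
any interval whose probability underflows contributes a large finite penalty
(−1e10) with zero gradient instead of −∞, keeping line searches finite; the
reported log-likelihood is re-evaluated exactly at the optimum.

A computational note: the per-observation grid probabilities depend only on
the (covariate pattern, interval) combination, of which cohort data contain
a few hundred; they are computed once per combination per evaluation and
gathered, which makes a 2000-pair fit take seconds.

## Estimation and uncertainty

Maximisation is quasi-Newton (L-BFGS-B) on the unconstrained vector
(log k, beta0, beta, log σ_p, log σ_i), with the analytic gradient obtained
by propagating posterior node weights through the nested log-sum-exp — the
gradient is verified against finite differences in the tests. A
deterministic warm start at 5 quadrature nodes precedes the full-order
stage; there are no random restarts. Initial values: shape and intercept
from a censoring-ignorant Weibull moment fit of interval midpoints, betas 0,
sigmas 0.1.

Convergence: the default projected-gradient tolerance is 1e-6. Cohort-scale
log-likelihoods are of magnitude 1e3–1e4, so an absolute gradient norm much
below that is not attainable in double precision; when the line search
aborts near the optimum the fit is polished with plain BFGS and accepted if
the final gradient inf-norm is ≤ max(1e-3, 1e-4·|loglik|). Anything else is
flagged `converged=False`, as are boundary outcomes (e.g. every response in
one open-ended category with no covariate contrasts, where the scale
parameter diverges — returned flagged, never silently).

The covariance of the estimates is the inverse of a central-finite-difference
Hessian of the analytic gradient at the optimum, on the unconstrained scale;
hazard-ratio CIs are Wald intervals exp(beta ± z·se). Frailty-SD
uncertainties, if needed, follow by the delta method from the log-sigma
entries.

## Nonparametric curves

The Turnbull NPMLE restricts probability mass to the innermost intervals
(maximal intersections of observation intervals) and maximises by the
self-consistency EM from a uniform initialisation; the EM log-likelihood is
monotone (asserted iteration-wise in tests) and masses sum to 1 ± 1e-10.
Within an innermost interval the NPMLE is undefined; curves are rendered
flat with the drop at the interval's right endpoint — a conventional,
conservative display. A midpoint Kaplan–Meier estimator (finite intervals →
midpoints as event times, right-censored categories → censored at the left
bound) is kept for comparison because grouped-data survival curves are often
presented as Kaplan–Meier; on unambiguous (effectively uncensored) data the
two coincide, which is tested.

## Descriptive summaries

Stratum means and SDs use midpoint coding: interior categories contribute
their stated value; open categories contribute a policy value, by default
the stated boundary (4.0 / 6.0 / 10.0 h), configurable to the interval
endpoint instead. Midpoint coding is used *only* for descriptives — the
likelihood never sees imputed points. The coding biases stratum means by
less than half a category width relative to the latent mean (tested on
synthetic data), and the open-category policy is the main sensitivity; the
model-implied expectation of the coded value can be computed exactly and is
what the fidelity test compares against, with cluster-robust standard
errors because twins' and repeated responses are correlated. Trend
statistics convert correctly: a drop from 7.57 to 7.39 h over 1975–2011 is
10.8 min, i.e. 0.30 min per year of follow-up.

## Synthetic cohort

The generator mirrors the study design: same-gender twin pairs (shared
birth year), birth years uniform on 1880–1957, four waves with
eligibility — 1975/1981: the full cohort, adult at survey; 1990: born
1930–1957; 2011: born 1945–1957 — and independent Bernoulli participation
at the waves' response rates (0.89, 0.84, 0.77, 0.72). Latent durations are
inverse-CDF draws from the Weibull model; categories come from the wave's
scheme. Generating hazard ratios default to the published point estimates
(1.11, 1.41, 1.62; 1.24, 1.23; 1.13) and the baseline is calibrated so the
reference stratum (female, 18–34, born before 1900) has latent mean 7.7 h
and SD 0.9 h at zero frailty, matching the reported descriptive anchor near
7.7 h. Each pair draws from its own substream keyed by (seed, pair index),
so enlarging a cohort extends it without reshuffling — simulation outputs
are byte-identical across reruns.

What the generator does **not** emulate: the real age pyramid (birth years
are uniform), mortality/attrition linking waves (participation is
independent per wave), zygosity, non-response correlated with sleep, and
any period effects beyond the cohort/age structure. Passing recovery tests
therefore show that *if* data follow the assumed model at these sample
sizes, the estimator finds the truth — they cannot validate the model
against the real cohort, whose data are not public.

## Problem sizes and replication choices

The recovery harness fits 50 replicate cohorts of 2000 pairs at 15
quadrature nodes; per-coefficient 95% CI coverage of the generating hazard
ratios is required to be ≥ 90% and the mean absolute relative error of the
HR estimates < 10% (observed ≈ 2–3%). Likelihood cross-checks use ≤ 30
observations per instance so Monte Carlo with 200,000 draws is sharp. The
acceptance script uses one 2000-pair cohort.

## Known limitations

- The frailty distribution (normal on the log-hazard) and the
  proportional-hazards Weibull form are modelling choices; the package does
  not implement gamma-frailty or AFT alternatives.
- No confidence bands for the NPMLE; no smoothing.
- No survey weights or nonresponse adjustment.
- Frailty SDs are weakly identified in small cohorts and can hit the zero
  boundary; either level can be pinned (`fix_sigma_pair` / `fix_sigma_ind`).
- Ages are computed as survey year minus birth year (no month-level data),
  so group boundaries can be off by up to a year for individuals.
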
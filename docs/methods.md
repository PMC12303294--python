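# Methods

## The model family

The package treats the age-specific incidence rate I(t) — new cases per
100,000 persons per unit time at age class t, mathematically the hazard
of disease onset — as the observable footprint of a multistage process:
disease requires r discrete, irreversible, rate-limiting events
(mutations, epimutations, rearrangements) that must occur in one
specific order, the i-th at rate k_i per unit time.  When every event is
individually rare over a lifetime, the probability that the first r−1
events have all occurred in order by age t is
(k_1 … k_{r−1}) t^(r−1) / (r−1)!, and the r-th event then strikes at
rate k_r, giving the power-law hazard

    I(t) = k t^(r−1),        k = k_1 … k_r / (r−1)!,

i.e. the linear log-log model `ln I = (r−1) ln t + ln k`.  The slope of
a log-log plot therefore counts rate-limiting steps (minus one) and the
intercept aggregates their rates.

Two four-parameter generalisations bend the log-log line:

* convex-upwards: `ln I = a0 + a1 ln t + ln(1 − a2 t^a3)` (incidence
  falls away from the power law at older ages);
* concave-upwards: `ln I = a0 + a1 ln t + ln(1 + a2 t^a3)` (incidence
  accelerates past it).

Either curvature admits two mechanistic readings, implemented in
`map_curved_to_mechanistic`:

* **heterogeneity** — two population subgroups (or pathways) with
  sequence probabilities k_p, k_q whose risks scale as t^p and t^q:
  a0 = ln k_p, a1 = r + p − 1, a2 = k_q/k_p, a3 = q − p.  Since a1 pins
  down only r + p, the caller must fix one of (r, p); the function
  refuses to guess.
* **age-related effect** — a single pathway modified by a decelerating
  (convex: k_d, d) or accelerating (concave: k_a, a) factor:
  a2 = k_d/k, a3 = d − r + 1, with r = a1 + 1 read from the fit.

A third reading, `decompose_slope`, covers per-event rates that grow
with age as t^h: the observed slope is then h + r − 1.  h is not
identifiable from a single series, so it defaults to 0 and must be
supplied explicitly (e.g. to attribute a male/female slope difference to
gender-specific rate acceleration at equal step count).

## Age classes and time rescaling

Registry age groups have unequal widths (0–14, 15–39, then five-year
bands), but the model is fitted on consecutive integer age *classes*
1, 2, 3, … with unit log-time spacing.  This is harmless for the step
count: rescaling the time axis by w multiplies every per-event rate's
time unit, dividing k by w^(r−1) — the intercept shifts by
−(r−1) ln w while the slope is untouched (`rescale_time`; the property
test checks prediction invariance on the rescaled axis).  If the first
age group has zero incidence in **both** genders it is dropped and the
next group becomes class 1 (`assign_age_classes`); a zero in one gender
only is kept and excluded at fit time for that gender, with a logged
warning.  Interior zeros are likewise excluded point-wise (log of zero),
never imputed.

## Fitting

* **Linear**: ordinary least squares of ln I on ln t
  (`scipy.stats.linregress`); r = slope + 1, k = exp(intercept).
  Requires ≥ 3 positive-incidence classes.
* **Curved** (`fit_curved`): a hybrid scheme.  For each anchor prefix of
  the earliest m points (m = 3 … n−2; early, because the curvature term
  grows with t in both families over the coefficient ranges of
  interest), (a0, a1) come from an anchor OLS and (a2, a3) from a second
  linear regression on algebraically transformed later residuals
  d = ln I − (a0 + a1 ln t): concave points satisfy
  ln(e^d − 1) = ln a2 + a3 ln t, convex points
  ln(1 − e^d) = ln a2 + a3 ln t.  With exactly two later points this
  stage is the exact two-equation solution.  Because no prefix is
  entirely curvature-free, each staged estimate then seeds a
  Levenberg–Marquardt refinement of all four coefficients on the
  ln-scale residuals (a2 optimised as log a2 to stay positive; the
  convex domain 1 − a2 t^a3 > 0 enforced by penalty); the anchor with
  the lowest refined SSR wins.  Plain alternation of the two linear
  stages was tried first and oscillates without converging; the
  multi-start refinement recovers noise-free generating coefficients to
  ~1e−12 across the coefficient ranges a1 ∈ [−2, 3], a2 ∈ [0.005, 0.8],
  a3 ∈ [0.1, 3].  Small a3 (≲ 0.2) makes the curvature term nearly
  constant in ln t and the problem ill-conditioned, which is why the
  refinement is given a generous evaluation budget.
* Residual signs incompatible with the requested curvature (≥ 2
  compatible later points required) raise `CurvatureMismatchError` — a
  purely linear series has no curvature to fit, although a degenerate
  a2 ≈ 0 fit is also accepted when floating noise produces one.
* **Selection** (`select_model`): all three fits are attempted (curved
  failures recorded, not fatal) and ranked by R² on the ln scale,
  1 − SS_res/SS_tot.  The two-parameter linear model is preferred unless
  a four-parameter curved fit beats it by more than `tie_tolerance`
  (default 0.005) — a parsimony tie-break, so the selector never
  prefers a curved model whose global R² is below the linear one.
  Confidence intervals are out of scope; R² is the selection criterion
  throughout.

## Synthetic data

`generate_series` evaluates a chosen model on age classes (default 1..8,
mirroring the eight registry groups) and adds independent Gaussian noise
of standard deviation `noise_sd` on the ln-incidence scale —
multiplicative lognormal noise on the natural scale, chosen because
fitting happens on the log scale, keeping the error model conjugate to
the estimator.  No claim is made that registry rates have
lognormal errors (a Poisson count component is absent); the generator
tests estimator correctness, self-consistency and selection behaviour,
not robustness to real registry noise, age-group widths, cohort effects
or competing risks.  The default noise_sd used by the noisy studies is
0.05 on ln I (≈ 5% multiplicative), a round value chosen to be of the
order of the scatter a near-1 R² fit leaves on an 8-point series.

`simulate_cohort` draws each individual's onset age as the sum of r
sequential exponential waiting times (event i's clock starts when event
i−1 completes — the required order realised directly, not by thinning
unordered events), censored at `max_age`.  One seeded NumPy generator
draws the (n, r) waiting-time matrix in a single call, so results are
reproducible and independent of any iteration order.
`estimate_hazard` is a binned occurrence/exposure estimator: events in
bin / person-time at risk in bin, over `n_bins` equal-width bins
partitioning (0, max_age]; censored individuals contribute exposure.
Zero-exposure bins are flagged undefined (NaN), never dropped silently.
`hazard_loglog_slope` regresses ln hazard on ln bin-midpoint weighted by
bin event counts (the inverse variance of a log-Poisson rate), using
bins with at least `min_events` events (default 5; the log of a 1–2
count bin is badly biased).

### What the simulator can and cannot confirm

The power law is the rare-event limit.  The exact hazard of the
sequential-exponential process falls below k t^(r−1) by a factor
≈ 1/Σ_{j<r}(k t)^j/j! (equal rates), a relative depletion of order k·t.
Two consequences shape the power-law agreement study (per-event rarity
k_i·max_age, one 200,000-individual cohort per r, seed 0, 10 bins):

* the expected onset count is n·(k_i·max_age)^r / r!, so at rarity 0.2
  a cohort yields ≈ 4000 events for r = 2, ≈ 270 for r = 3 and ≈ 13 for
  r = 4.  A power-law exponent carried by e events has standard error
  ≈ r/√e: ≈ 0.03, 0.18 and 1.1 respectively.  The r = 4 condition
  therefore cannot support a slope estimate at this cohort size — the
  corresponding check is expected to fail and is left in place as an
  honest record of that limit, with the arithmetic above as the
  explanation.
* for r = 2 the thousands of events resolve per-bin hazard levels to a
  few percent, tighter than the ~10–16% depletion at rarity 0.2; r = 2
  is therefore run at rarity 0.1, where the depletion (≈ 10% at the
  oldest ages) stays below the ≈ 22% three-standard-error resolution of
  its late bins, while r = 3 and 4 keep rarity 0.2 because they need
  every event and their sparse bins resolve nothing finer.

## Combined-gender slope algebra

The both-genders rate is the unweighted arithmetic mean
I_fm = (I_f + I_m)/2 (no population weighting, matching the convention
under which the intermediacy algebra is derived).  Between two age
classes the combined log-log slope satisfies two exact identities,

    S_fm = S_f + ln[(1 + I_m2/I_f2)/(1 + I_m1/I_f1)] / Δln t
         = S_m + ln[(1 + I_f2/I_m2)/(1 + I_f1/I_m1)] / Δln t,

so whichever gender rises faster pulls the combined slope strictly
between the two: S_f < S_fm < S_m whenever S_f < S_m, with equality
throughout when the gender series are proportional.  `slope_triple`
computes the combined slope directly from the mean series *and* through
both corrections, raising if the routes disagree beyond floating
tolerance — a permanent internal consistency check.  For multi-point
series the two-point algebra is applied to consecutive class pairs;
intermediacy of full OLS slopes is an empirical regularity, not a
theorem, so it is checked and reported but only the pairwise version is
asserted as an invariant.

## Numerical conventions

* Natural logarithms throughout; incidence is used as-is in units of
  cases per 100,000 (the intercept absorbs the unit).
* Fitted r is real-valued and never silently rounded; reports carry the
  point value plus the bracketing integer range ("3 to 4 steps").
* Rare-event validity: `MultistageRates.check_rare` warns (does not
  raise) when any k_i·t_max ≥ 1, since validity depends on the horizon,
  not the rates alone; convex-domain violations (a2·t^a3 ≥ 1) are
  errors at evaluation time for the same reason.
* R² with zero observed variance is undefined (error) except for the
  perfect-fit constant series in `fit_linear`, which reports 1.
* Degenerate two-point curvature stages use the exact algebraic
  solution; OLS otherwise.

## Problem sizes

The studies in the test suite use: 8 age classes per series; 500
replicates for noisy slope recovery; 300 replicates per family for
selection accuracy; 10,000 random draws for the slope-identity and
intermediacy properties; one 200,000-individual cohort per step count
for power-law agreement.  The full suite runs in a few minutes on one
core.

## Known limitations

* The hybrid curved fit reports no uncertainty; with 8 points and 4
  parameters the curved models are close to saturation and R²
  comparisons between them are fragile — hence the parsimony tie-break.
* (r, p) in the heterogeneity reading and h in the time-varying-rate
  reading are not identifiable from a single series; the API forces the
  caller to fix them rather than hiding the choice.
* The simulator covers the stated event-sequence mechanism only: no
  birth-cohort effects, competing mortality, population weighting, or
  diagnosis lag.
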
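# multistage

Multistage-carcinogenesis modelling of age-specific cancer incidence:
fitting and interpreting log-log incidence models, simulating cohorts
that accrue ordered rate-limiting events, and analysing the slope
algebra of gender-combined incidence series.

## The science

If a cancer requires `r` discrete, irreversible, rate-limiting events
(driver mutations, epimutations, rearrangements) that must occur in a
specific order, the i-th at rate `k_i` per unit time, and every event is
individually rare over a lifetime, the age-specific incidence rate
(hazard) follows a power law in age:

    I(t) = k t^(r-1),    k = k_1 k_2 ... k_r / (r-1)!

so that `ln I(t) = (r-1) ln t + ln k`: the slope of a log-log plot
counts rate-limiting steps minus one, and the intercept is the log of
the aggregated probability of the ordered sequence.  Cancers whose
log-log plots bend are covered by two four-parameter generalisations —
convex-upwards `ln I = a0 + a1 ln t + ln(1 - a2 t^a3)` and
concave-upwards `ln I = a0 + a1 ln t + ln(1 + a2 t^a3)` — each readable
either as two population subgroups with probabilities `k_p = exp(a0)`,
`k_q = a2 k_p` and age-scaling exponents `p`, `q = a3 + p`, or as a
single pathway modified by an age-related decelerating/accelerating
factor.  See `docs/methods.md` for the full model account, fitting
algorithm, and limitations.

The package is aimed at epidemiological modellers who want to fit these
models to registry-style age-class incidence tables (CSV), interpret the
coefficients mechanistically, and validate the whole chain against
simulated cohorts in which the event-sequence mechanism is true by
construction.

## Worked example

Generate a noisy synthetic series from the male-bladder linear
coefficients (slope 2.644, intercept −1.236), refit it, and interpret:

```sh
$ multistage --seed 0 synth --model linear --params "2.644,-1.236" \
      --noise-sd 0.05 --cancer bladder --gender male --out bladder.csv
$ multistage fit bladder.csv --out fits
bladder/male: chose linear (R^2 = 0.9998)
wrote fits_linear.csv
$ multistage interpret bladder.csv --narrative
--- bladder/male
Fitted number of rate-limiting steps: r = 3.663 (i.e. 3 to 4 discrete events).
Aggregated ordered-sequence probability: k = 0.2883 per unit time.
```

Reading: the recovered slope 2.663 implies r ≈ 3.7, i.e. three to four
sequential rate-limiting steps, with overall ordered-sequence
probability k = exp(intercept) ≈ 0.29 per unit time — the 5% log-scale
noise perturbs the generating values (r = 3.644, k = 0.2905) only in
the third digit.

The cohort simulator closes the loop from the opposite direction —
individuals accrue ordered exponential waiting-time events and the
binned hazard of the resulting onset ages reproduces `k t^(r-1)`:

```sh
$ multistage --seed 0 simulate --rates "0.001,0.001,0.001" \
      --n 200000 --max-age 100 --bins 10 --out cohort.csv
27 onsets, 199973 censored
...
bin (90, 100]: events=9 hazard=4.501e-06
```

(here aggregate k = 5e-10, so the power-law hazard at t = 95 is
5e-10 × 95² ≈ 4.5e-6, matching the last bin).

The same operations are available as library functions
(`generate_series`, `fit_linear`, `fit_curved`, `select_model`,
`interpret_linear`, `simulate_cohort`, `estimate_hazard`,
`combine_genders`, `slope_triple`, ...); the CLI is a thin wrapper.

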
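# Methods

## Model and notation

Counts `Y_i` (one per time unit, normally a day) follow a Poisson law with
`log mu_i = alpha_s(i) + x_i beta + offset_i`. The strata `s` are calendar
cells — `year_month_dow` (day-of-week within month within year, the usual
time-stratified case-crossover referent scheme) or `year_month` — and the
`alpha_s` absorb everything that varies between cells: season, long-term
trend, weekly rhythm. Inference about `beta` therefore rests only on
within-stratum covariation of counts and exposures. The offset is a known
per-record log term for varying rate denominators (person-time, population
at risk); it defaults to zero.

Conditioning on the stratum totals `n_s` removes the `alpha_s`: given
`n_s`, the stratum's counts are multinomial with day probabilities
`p_i = exp(eta_i) / sum_{j in s} exp(eta_j)`, `eta_i = x_i beta + offset_i`.
The package maximizes

    l(beta) = sum_{s: n_s>0} [ sum_{i in s} Y_i eta_i - n_s log sum_{j in s} exp(eta_j) ]

omitting the beta-free multinomial coefficient, so reported log-likelihoods
are comparable across conditional fits of the same data but differ from the
full Poisson log-likelihood by the eliminated terms
`sum_s (n_s log n_s - n_s) - sum_i log Y_i!` (an identity that holds
exactly at the joint MLE and is asserted in the test suite). Strata with
`n_s = 0` contribute nothing and are dropped before fitting.

## Estimation

Newton–Raphson from `beta = 0` with analytic score
`g = X'(Y - mu)`, `mu_i = n_s p_i`, and information
`I = X' diag(mu) X - Xbar' diag(n_s) Xbar`, `Xbar_s = sum_{i in s} p_i x_i`.
The objective is concave, so plain Newton with step-halving (max 30
halvings on any non-increasing step) is reliable; convergence requires both
a relative log-likelihood change below 1e-9 and a maximum absolute score
below 1e-6 (defaults in `FitOptions`). Per-stratum log-sum-exp subtraction
of the within-stratum maximum `eta` keeps the weights finite under large
offsets or covariates. The coefficient covariance is the inverse observed
information at the maximum; 95% intervals use z = 1.959964.

Two guards convert ill-posed problems into typed errors rather than wrong
numbers:

* **Identifiability** — before fitting, the within-stratum-centered design
  must have full column rank (SVD with a scale-relative tolerance);
  deficiency raises `NonIdentifiableError` naming the aliased columns.
* **Separation** — a likelihood with no finite maximum flattens out, so the
  gradient criterion alone would "converge" at an arbitrary large beta.
  The fitter raises `ConvergenceError` if any |beta| exceeds
  `FitOptions.beta_max` (default 25, appropriate for covariates on roughly
  unit scale; rescale or raise it for tiny covariate units) or if the
  smallest information eigenvalue at the optimum falls below 1e-4 of its
  value at beta = 0.

## The equivalent formulations

`expand_casecrossover` emits the semi-expanded case-crossover layout: one
matched set per day with events, containing every day of that stratum, the
event day flagged as case, and the whole set weighted by the event day's
count. `fit_conditional_logistic` maximizes the weighted matched-set
likelihood `sum_sets w [eta_case - log sum_set exp(eta)]` directly from
those rows with its own damped Newton iteration — a deliberately separate
code path from the stratified-count fitter, used as a mutual cross-check.
`fit_unconditional_poisson` is IRLS (statsmodels GLM) on intercept +
(S-1) stratum indicators + covariates, restricted to active strata, and
refuses more than `stratum_cap` (default 2000) strata, since each IRLS step
inverts a matrix of order S. Its `n_params` counts the covariates plus the
S-1 non-reference stratum indicators — the convention used when quoting
"421 coefficients" for a 420-stratum, 2-covariate design — while the
conditional fits count covariate terms only.

All three agree in estimates and standard errors to numerical tolerance on
any dataset where all three are fit; the test suite asserts pairwise
agreement to 1e-5 on 200 randomized small datasets and against a
derivative-free optimizer of the conditional objective.

## Overdispersion

`estimate_dispersion` returns `psi = Pearson X^2 / df` with
`X^2 = sum (Y_i - mu_i)^2 / mu_i` over active-stratum records and
`df = N_active - S_active - p`: the eliminated baselines still consume one
df per active stratum, mirroring the equivalent unconditional model.
Quasi-Poisson inference (`FitResult.with_dispersion`) multiplies the
covariance by psi — every SE by sqrt(psi) exactly — and changes no point
estimate. psi is reported as computed, never floored at 1; applying it is
the caller's choice. The Pearson estimator is known to be unreliable when
events per stratum are sparse, so a warning is emitted when the mean events
per active stratum falls below 5; no sparse-data correction is attempted.

## Autocorrelation

Serial correlation in the counts violates the conditional independence the
case-crossover formulation assumes, even with day-of-week in the strata.
`fit_autocorr_adjusted` uses the lagged-residual device for count series:
fit the base model, form standardized residuals (Pearson by default,
deviance optional) in calendar order, append the previous day's residual as
a covariate, and refit; the lag coefficient and its CI are reported beside
both fits. Choices made here, configurable where they were genuinely open:

* lagging runs across calendar days, not within strata (the underlying
  series' serial dependence ignores stratum boundaries); the observation
  spacing defaults to one day and is declarable for other cadences;
* a missing lag (series start, gap, previous day in a zero-event stratum)
  is filled with 0, the residual's null expectation;
* one augmentation step, not an iterated scheme — the adjusted model adds
  exactly one coefficient per lag; `n_lags` > 1 appends further lags;
* if the base fit is exact (all residuals at machine zero) the lag column
  carries no information, and the adjusted result is the base fit plus a
  zero lag coefficient rather than a spurious rank failure.

## Simulator

`simulate(SimulationConfig)` generates the canonical design: ten years
(`round(365.25 * n_years)` = 3652 days from a configurable start,
2000-01-01 by default, leap days included) of daily counts; `n_covariates`
= 7 covariates multivariate normal with exchangeable pairwise correlation
0.25 (positive definite iff r > -1/(k-1), validated); covariates centered
and scaled to **unit sample SD**, so `rr_per_sd` = 1.05 is exact in-sample;
`log mu = log(baseline_rate) + sum_k log(rr_per_sd) x_ik` with baseline 1,
10 or 100 events/day for small/medium/large cities; Poisson counts.
`n_series` > 1 stacks independent cities with city-specific strata. The
clean design has no stratum-level structure; optional knobs inject
departures to exercise the machinery: `overdispersion` (negative-binomial
size), `ar1`/`ar1_sd` (shared log-scale AR(1) term), `stratum_sd`
(stratum-constant intercept shifts — a seasonal confounder that the
conditioning must absorb, and does, as a test asserts). A single seeded
`numpy` Generator drives everything; replicate r of a recovery study uses
`seed + r`, so studies are reproducible and parallelizable by seed.

What the simulator does *not* emulate: real weather's nonlinear and lagged
mortality dependence, slow demographic trends inside strata, holiday
effects, or measurement error in exposures. Passing recovery tests
therefore demonstrate correctness of the estimator under its own
assumptions, not robustness to the misspecifications real data carry.

`recovery_study` fits the conditional model to each replicate and reports
per-covariate mean estimate, empirical SE, mean model SE, and empirical 95%
CI coverage; replicate failures are tolerated up to 20% and counted.

## Problem sizes used in the shipped checks

The recovery calibration runs the full design (3652 days, baseline 100,
7 covariates, 50 replicates; under a second in total — the conditional
fitter's per-replicate cost is a few Newton steps over 840 strata). The
dispersion calibration uses 100 replicates of a 2-year, baseline-10,
month-stratified design: correct specification is all that matters for
psi ≈ 1, so the smaller series is a pure economy. The three-way
equivalence check uses 200 random datasets of 2–6 strata × 2–7 days,
counts 0–20; draws with no finite or identifiable MLE are resampled, since
the equivalence theorem speaks only to datasets all three models can fit.

## Known limitations

* No random-stratum-effect (mixed) variant is offered: trading the
  conditioning for a Gaussian stratum distribution buys precision only by
  assuming away between-stratum confounding, and is deliberately out of
  scope.
* Covariates arrive pre-built; no spline/distributed-lag construction.
* The Pearson dispersion estimate degrades with sparse strata (warning
  only, no correction).
* The lagged-residual adjustment is first-order and one-step; no ARMA
  structure or GEE working correlation.
* The unconditional reference fitter is dense and capped; it exists as an
  oracle and for small designs, not as the production path.
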
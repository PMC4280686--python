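# condpoisson

Conditional Poisson regression for time-stratified count time series — the
model behind the time-stratified case-crossover design used throughout
environmental epidemiology to relate daily counts of deaths or
hospitalizations to short-term variation in air pollution and weather.

## The problem and the model

A city's daily death count `Y_i` is modelled as Poisson with

```
log mu_i = alpha_s(i) + x_i * beta + offset_i
```

where `x_i` holds the exposures and covariates for day `i` (ozone,
temperature, ...) and `alpha_s` is a free baseline for the calendar stratum
`s` containing the day — typically day-of-week within month within year, so
slow seasonal drift and weekly rhythm are controlled by design. With five
years of data that is 420 nuisance baselines. Rather than estimating them
(the *unconditional* Poisson model) or expanding every death into a matched
case-control set (the *conditional logistic* case-crossover analysis), the
**conditional Poisson model** conditions on each stratum's event total
`n_s = sum_{i in s} Y_i`, which eliminates the `alpha_s` exactly. Each
stratum becomes a multinomial, and the log-likelihood is

```
l(beta) = sum_{s : n_s > 0}  [ sum_{i in s} Y_i * eta_i  -  n_s * log sum_{j in s} exp(eta_j) ],
          eta_i = x_i * beta + offset_i.
```

All three formulations maximize the same profile likelihood and give
identical covariate estimates and standard errors; the conditional Poisson
form is simply the cheapest, and — unlike conditional logistic — it
supports quasi-Poisson overdispersion (Pearson chi-squared over residual
df), lagged-residual adjustment for serial correlation, rate offsets, and
residual diagnostics. This package provides all three fitters (the other
two double as cross-checking oracles), the semi-expanded case-crossover
data layout, a simulator reproducing the canonical study design, and a CLI.

## Worked example

Simulate five years of daily counts (baseline 50 events/day, three
covariates pairwise correlated at 0.25, true rate ratio 1.05 per covariate
SD) and fit every formulation:

```
$ condpoisson simulate --config sim.yaml --out demo.csv
wrote 1826 records to demo.csv (true log-RR per SD = 0.0487902)

$ condpoisson fit --input demo.csv --count-col count \
    --covar x1 --covar x2 --covar x3 --scheme year_month_dow \
    --exposure x1 --delta 1 --model all --quasipoisson --autocorr 1
                model  pct_change  pct_lo95  pct_hi95  dispersion  n_params note
 conditional logistic         5.9      5.10      6.71     1.00000         3
unconditional Poisson         5.9      5.10      6.71     1.00000       422
  conditional Poisson         5.9      5.10      6.71     1.00000         3
     + overdispersion         5.9      5.13      6.67     0.91614         3
   + auto-correlation         5.9      5.10      6.71     1.00000         4
```

Reading the table: the exposure `x1` raises the daily rate by 5.9%
(95% CI 5.10–6.71%) per standard deviation — the truth is 5% — and the
three plain formulations agree to every printed digit, as the equivalence
theorem says they must. The unconditional fit needed 422 coefficients
(3 covariates + 419 stratum indicators beyond the reference) to say the
same thing the conditional fit said with 3. The estimated dispersion on
this replicate is 0.92 (a correctly specified Poisson draw, so psi ≈ 1),
and the lag-1 residual adjustment adds one coefficient and moves nothing —
the simulated counts are serially independent.

The same analysis in Python:

```python
from condpoisson import read_series, build_index, fit_conditional_poisson, percent_change

series = read_series("demo.csv", "csv",
                     {"count": "count", "covariates": ["x1", "x2", "x3"]})
index = build_index(series)
fit = fit_conditional_poisson(series, index)
print(fit.summary_frame())          # term, estimate, se, z, lo95, hi95
print(percent_change(fit.beta[0]))  # percent change per unit of x1
```

`condpoisson expand` writes the semi-expanded case-crossover layout (one
weighted matched set per day with events) for use with external software,
and `condpoisson recover` runs a simulate-and-refit calibration study.

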
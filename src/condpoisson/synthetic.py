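"""Simulated stratified count series and estimator-recovery studies.

The generator reproduces the statistical structure of a typical multi-year
environmental time-series study: ten years of daily counts, seven covariates
(exposures and confounders) drawn multivariate normal with exchangeable
pairwise correlation 0.25, each standardized so that one standard deviation
multiplies the event rate by 1.05, with baseline rates of 1, 10 or 100
events/day standing in for small, medium and large cities. Counts are
Poisson with log-mean equal to log(baseline) plus the linear effect sum.

Optional departures from that clean design — negative-binomial
overdispersion, a shared log-scale AR(1) term, stratum-level intercept
shifts (a seasonal confounder constant within strata) — exist to exercise
the dispersion, autocorrelation, and conditioning machinery.

``recovery_study`` turns the design into an estimator-validation harness:
simulate, fit the conditional Poisson model, and aggregate bias, empirical
vs model-based standard errors, and 95% CI coverage over replicates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .condfit import FitOptions, fit_conditional_poisson
from .data_model import StratifiedSeries, build_index, make_strata
from .errors import ConvergenceError, DataError

__all__ = ["SimulationConfig", "SimulatedSeries", "simulate", "recovery_study", "RecoverySummary"]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the simulation design.

    ``n_years`` years of daily data (rendered as round(365.25 * n_years)
    days from ``start``); ``n_series`` stacks that day set for multi-city
    designs, with strata made by city as well as calendar cell;
    ``rr_per_sd`` is the rate ratio per covariate standard deviation
    (covariates are standardized to unit sample SD so the per-SD effect is
    exact in-sample). ``overdispersion`` is a negative-binomial size
    parameter (variance mu + mu^2/size); ``ar1`` adds a shared log-scale
    AR(1) term with that lag-1 coefficient and stationary SD ``ar1_sd``;
    ``stratum_sd`` adds N(0, sd) intercept shifts constant within strata.
    """

    n_years: int = 10
    baseline_rate: float = 100.0
    n_series: int = 1
    n_covariates: int = 7
    covar_correlation: float = 0.25
    rr_per_sd: float = 1.05
    scheme: str = "year_month_dow"
    overdispersion: float | None = None
    ar1: float | None = None
    ar1_sd: float = 0.1
    stratum_sd: float = 0.0
    start: str = "2000-01-01"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 1 or self.n_series < 1 or self.n_covariates < 1:
            raise DataError("n_years, n_series and n_covariates must be >= 1")
        if self.baseline_rate <= 0:
            raise DataError("baseline_rate must be positive")
        if self.rr_per_sd <= 0:
            raise DataError("rr_per_sd must be positive")
        r, k = self.covar_correlation, self.n_covariates
        # exchangeable correlation matrix is positive definite iff
        # -1/(k-1) < r < 1
        if k > 1 and not (-1.0 / (k - 1) < r < 1.0):
            raise DataError(
                f"pairwise correlation {r} is not positive definite for "
                f"{k} covariates (need r > {-1.0 / (k - 1):.4f} and r < 1)"
            )
        if self.overdispersion is not None and self.overdispersion <= 0:
            raise DataError("overdispersion (negative-binomial size) must be positive")
        if self.ar1 is not None and not (-1.0 < self.ar1 < 1.0):
            raise DataError("ar1 must lie in (-1, 1)")

    @property
    def n_days(self) -> int:
        return int(round(365.25 * self.n_years))

    @property
    def true_beta(self) -> np.ndarray:
        return np.full(self.n_covariates, np.log(self.rr_per_sd))

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise DataError(f"unknown simulation config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass(eq=False)
class SimulatedSeries(StratifiedSeries):
    """A StratifiedSeries carrying its generating truth."""

    true_beta: np.ndarray = field(default_factory=lambda: np.zeros(0))
    config: SimulationConfig | None = None


def _standardize(x: np.ndarray) -> np.ndarray:
    """Center and scale each column to unit sample SD (ddof=1)."""
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    return (x - mu) / sd


def simulate(config: SimulationConfig) -> SimulatedSeries:
    """Draw one dataset under the configured design.

    Identical config (including seed) gives bitwise-identical output.
    """
    rng = np.random.default_rng(config.seed)
    k = config.n_covariates
    r = config.covar_correlation
    corr = np.full((k, k), r)
    np.fill_diagonal(corr, 1.0)
    chol = np.linalg.cholesky(corr)
    log_rr = np.log(config.rr_per_sd)

    dates_one = pd.date_range(config.start, periods=config.n_days, freq="D")
    all_dates, all_counts, all_cov, all_strata = [], [], [], []
    for city in range(config.n_series):
        x = rng.standard_normal((config.n_days, k)) @ chol.T
        x = _standardize(x)
        eta = np.log(config.baseline_rate) + x @ np.full(k, log_rr)

        strata = make_strata(dates_one, config.scheme)
        if config.n_series > 1:
            strata = np.asarray([f"c{city + 1}:{s}" for s in strata], dtype=object)
        if config.stratum_sd > 0:
            labels, codes = np.unique(strata, return_inverse=True)
            shifts = rng.normal(0.0, config.stratum_sd, size=len(labels))
            eta = eta + shifts[codes]
        if config.ar1 is not None:
            phi = config.ar1
            innov_sd = config.ar1_sd * np.sqrt(1.0 - phi**2)
            u = np.empty(config.n_days)
            u[0] = rng.normal(0.0, config.ar1_sd)
            eps = rng.normal(0.0, innov_sd, size=config.n_days - 1)
            for t in range(1, config.n_days):
                u[t] = phi * u[t - 1] + eps[t - 1]
            eta = eta + u

        mu = np.exp(eta)
        if config.overdispersion is not None:
            size = config.overdispersion
            counts = rng.negative_binomial(size, size / (size + mu))
        else:
            counts = rng.poisson(mu)

        all_dates.append(dates_one)
        all_counts.append(counts)
        all_cov.append(x)
        all_strata.append(strata)

    dates = pd.DatetimeIndex(np.concatenate([d.values for d in all_dates]))
    cov = pd.DataFrame(
        np.vstack(all_cov), columns=[f"x{j + 1}" for j in range(k)]
    )
    return SimulatedSeries(
        dates=dates,
        counts=np.concatenate(all_counts),
        covariates=cov,
        offsets=None,
        strata=np.concatenate(all_strata),
        true_beta=config.true_beta,
        config=config,
    )


@dataclass(eq=False)
class RecoverySummary:
    """Aggregated parameter-recovery results.

    ``table`` has one row per covariate: true log-RR, mean estimate, mean
    RR, empirical SE (SD of estimates across replicates), mean model SE,
    and empirical 95% CI coverage. ``estimates`` is the raw
    (n_ok, n_covariates) matrix of per-replicate coefficient estimates.
    """

    table: pd.DataFrame
    estimates: np.ndarray
    model_ses: np.ndarray
    n_replicates: int
    n_failed: int

    @property
    def mean_rr(self) -> float:
        """Mean estimated rate ratio per SD over replicates and covariates."""
        return float(np.mean(np.exp(self.estimates)))

    @property
    def overall_coverage(self) -> float:
        lo = self.estimates - 1.959964 * self.model_ses
        hi = self.estimates + 1.959964 * self.model_ses
        truth = self.table["true_beta"].to_numpy()
        return float(np.mean((lo <= truth) & (truth <= hi)))


def recovery_study(
    config: SimulationConfig,
    n_replicates: int,
    options: FitOptions | None = None,
    max_failure_fraction: float = 0.2,
) -> RecoverySummary:
    """Simulate-and-refit study of the conditional Poisson estimator.

    Replicate ``r`` uses seed ``config.seed + r`` so replicates are
    reproducible independently (and parallelizable by seed). A replicate
    whose fit fails is recorded and excluded; more than
    ``max_failure_fraction`` failures aborts the study.
    """
    if n_replicates < 2:
        raise DataError("n_replicates must be >= 2")
    betas, ses = [], []
    n_failed = 0
    for r in range(n_replicates):
        cfg = dataclasses.replace(config, seed=config.seed + r)
        data = simulate(cfg)
        try:
            fit = fit_conditional_poisson(data, build_index(data), options)
        except Exception:
            n_failed += 1
            continue
        betas.append(fit.beta)
        ses.append(fit.se())
    if n_failed > max_failure_fraction * n_replicates:
        raise ConvergenceError(
            f"{n_failed}/{n_replicates} replicate fits failed "
            f"(> {max_failure_fraction:.0%} allowed)"
        )
    est = np.asarray(betas)
    mse = np.asarray(ses)
    truth = config.true_beta
    lo = est - 1.959964 * mse
    hi = est + 1.959964 * mse
    table = pd.DataFrame(
        {
            "term": [f"x{j + 1}" for j in range(config.n_covariates)],
            "true_beta": truth,
            "true_rr": np.exp(truth),
            "mean_estimate": est.mean(axis=0),
            "mean_rr": np.exp(est).mean(axis=0),
            "empirical_se": est.std(axis=0, ddof=1),
            "mean_model_se": mse.mean(axis=0),
            "coverage95": ((lo <= truth) & (truth <= hi)).mean(axis=0),
        }
    )
    return RecoverySummary(
        table=table,
        estimates=est,
        model_ses=mse,
        n_replicates=n_replicates,
        n_failed=n_failed,
    )
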
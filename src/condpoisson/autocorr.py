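"""First-order autocorrelation adjustment via lagged residuals.

The case-crossover / conditional Poisson machinery assumes counts are
independent given the covariates and stratum baselines. Residual serial
correlation violates that assumption even when strata include day-of-week.
The adjustment here follows the lagged-residual idea for count time series:

1. fit the base conditional Poisson model;
2. compute standardized (Pearson, by default) residuals on active-stratum
   records, in calendar order;
3. build a lag-1 covariate equal to the previous calendar day's residual
   (zero — the residual's null expectation — where the previous day is
   absent or belongs to an inactive stratum);
4. refit with that covariate appended.

One augmentation step is performed by default (the lag coefficient adds one
reported parameter); the number of lags is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .condfit import (
    FitOptions,
    FitResult,
    fit_conditional_poisson,
    fitted_means,
)
from .data_model import StratifiedSeries, StratumIndex, build_index
from .errors import DataError, NonIdentifiableError

__all__ = ["AutocorrFit", "residuals", "fit_autocorr_adjusted"]

LAG_TERM = "resid_lag{k}"


@dataclass(eq=False)
class AutocorrFit:
    """Base and lag-augmented fits, plus the lagged-residual coefficient."""

    base: FitResult
    adjusted: FitResult
    rho: np.ndarray  # lag coefficients
    rho_ci: np.ndarray  # (n_lags, 2) 95% Wald bounds
    residual_kind: str

    @property
    def n_lags(self) -> int:
        return len(self.rho)


def residuals(
    fit: FitResult,
    series: StratifiedSeries,
    index: StratumIndex | None = None,
    kind: str = "pearson",
) -> np.ndarray:
    """Per-record residuals (NaN on records in zero-event strata).

    Pearson: (Y - mu)/sqrt(mu). Deviance:
    sign(Y - mu) * sqrt(2 [Y log(Y/mu) - (Y - mu)]) with 0*log(0) = 0.
    """
    if index is None:
        index = build_index(series)
    mu = fitted_means(fit, series, index)
    y = series.counts.astype(float)
    ok = np.isfinite(mu)
    out = np.full(series.n_records, np.nan)
    if kind == "pearson":
        out[ok] = (y[ok] - mu[ok]) / np.sqrt(mu[ok])
    elif kind == "deviance":
        ym, mm = y[ok], mu[ok]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.divide(ym, mm, out=np.ones_like(ym), where=mm > 0)
            ylog = np.where(ym > 0, ym * np.log(ratio), 0.0)
        dev = 2.0 * (ylog - (ym - mm))
        out[ok] = np.sign(ym - mm) * np.sqrt(np.clip(dev, 0.0, None))
    else:
        raise DataError(f"unknown residual kind {kind!r} (pearson or deviance)")
    return out


def _lag_covariates(
    series: StratifiedSeries, resid: np.ndarray, n_lags: int, time_step: pd.Timedelta
) -> np.ndarray:
    """Lagged residuals aligned on calendar time; 0 where the lag is missing."""
    dates = series.dates
    if dates.has_duplicates:
        raise DataError("duplicate dates: the lagged-residual covariate is undefined")
    pos = pd.Series(np.arange(len(dates)), index=dates)
    lags = np.zeros((len(dates), n_lags))
    for k in range(1, n_lags + 1):
        prev = dates - k * time_step
        found = pos.reindex(prev)
        have = found.notna().to_numpy()
        src = found.to_numpy()
        src_idx = src[have].astype(int)
        vals = resid[src_idx]
        vals = np.where(np.isfinite(vals), vals, 0.0)
        col = np.zeros(len(dates))
        col[have] = vals
        lags[:, k - 1] = col
    return lags


def fit_autocorr_adjusted(
    series: StratifiedSeries,
    index: StratumIndex | None = None,
    n_lags: int = 1,
    residual_kind: str = "pearson",
    time_step: pd.Timedelta | str = "1D",
    options: FitOptions | None = None,
    base_fit: FitResult | None = None,
) -> AutocorrFit:
    """Conditional Poisson fit with lagged-residual autocorrelation terms.

    ``time_step`` declares the spacing between consecutive observations
    (default one day); when the series has gaps the lag is simply absent
    (filled with 0) across them. Lagging runs across calendar time, not
    within strata: serial correlation in the underlying counts does not
    respect stratum boundaries.
    """
    if index is None:
        index = build_index(series)
    if n_lags < 1:
        raise DataError("n_lags must be >= 1")
    time_step = pd.Timedelta(time_step)
    if time_step <= pd.Timedelta(0):
        raise DataError("time_step must be positive")

    base = base_fit or fit_conditional_poisson(series, index, options)
    resid = residuals(base, series, index, kind=residual_kind)
    lags = _lag_covariates(series, resid, n_lags, time_step)

    lag_names = [LAG_TERM.format(k=k) for k in range(1, n_lags + 1)]
    aug = series
    for j, name in enumerate(lag_names):
        aug = aug.with_covariate(name, lags[:, j])

    # residuals at machine scale mean a perfect fit; the lag terms then
    # carry no information and would only trip the rank check
    degenerate = bool(np.all(np.abs(lags) < 1e-7))
    if degenerate:
        # perfect fit: residuals are identically zero, so the lag terms
        # carry no information; report the base fit with zero lag
        # coefficients rather than failing the rank check
        p = len(base.beta)
        beta = np.concatenate([base.beta, np.zeros(n_lags)])
        cov = np.zeros((p + n_lags, p + n_lags))
        cov[:p, :p] = base.cov
        adjusted = FitResult(
            beta=beta,
            names=base.names + lag_names,
            cov=cov,
            loglik=base.loglik,
            n_params=base.n_params + n_lags,
            converged=base.converged,
            n_iter=0,
            model_kind="cond_poisson",
        )
    else:
        try:
            adjusted = fit_conditional_poisson(aug, index, options)
        except NonIdentifiableError as exc:
            raise NonIdentifiableError(
                f"lag-augmented design is not identifiable: {exc}", aliased=exc.aliased
            ) from exc

    p = len(base.beta)
    rho = adjusted.beta[p:]
    ci = adjusted.conf_int()[p:]
    return AutocorrFit(
        base=base,
        adjusted=adjusted,
        rho=rho,
        rho_ci=ci,
        residual_kind=residual_kind,
    )
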
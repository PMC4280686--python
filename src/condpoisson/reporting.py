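"""Tidy coefficient tables and multi-model comparison reports."""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .autocorr import fit_autocorr_adjusted
from .condfit import (
    FitOptions,
    FitResult,
    estimate_dispersion,
    fit_conditional_poisson,
    percent_change,
)
from .data_model import StratifiedSeries, StratumIndex, build_index
from .errors import StratumCapError
from .reference_models import expand_casecrossover, fit_conditional_logistic, fit_unconditional_poisson

__all__ = ["coefficient_table", "compare_models", "ModelComparison"]


def coefficient_table(fit: FitResult, delta: dict[str, float] | float | None = None) -> pd.DataFrame:
    """Summary frame with optional percent-change columns.

    ``delta`` maps term name -> reporting increment (or one increment for
    all terms); percent change is 100*(exp(delta*beta)-1), with the same
    transform applied to the Wald bounds.
    """
    out = fit.summary_frame()
    if delta is not None:
        if not isinstance(delta, dict):
            delta = {t: float(delta) for t in fit.names}
        deltas = np.array([delta.get(t, np.nan) for t in fit.names])
        out["delta"] = deltas
        for col_src, col_dst in (("estimate", "pct_change"), ("lo95", "pct_lo95"), ("hi95", "pct_hi95")):
            out[col_dst] = 100.0 * np.expm1(deltas * out[col_src].to_numpy())
    return out


@dataclass(eq=False)
class ModelComparison:
    """Side-by-side model comparison for one exposure term."""

    table: pd.DataFrame
    fits: dict
    max_abs_beta_diff: float

    def to_json(self, **kwargs) -> str:
        payload = {
            "comparison": self.table.to_dict(orient="records"),
            "max_abs_beta_diff": self.max_abs_beta_diff,
            "fits": {k: f.to_dict() for k, f in self.fits.items()},
        }
        return json.dumps(payload, **kwargs)


def compare_models(
    series: StratifiedSeries,
    index: StratumIndex | None = None,
    exposure: str | None = None,
    delta: float = 1.0,
    quasipoisson: bool = True,
    autocorr_lags: int = 1,
    stratum_cap: int = 2000,
    options: FitOptions | None = None,
) -> ModelComparison:
    """Fit all formulations and report the exposure effect per increment.

    Rows (in order): conditional logistic, unconditional Poisson,
    conditional Poisson, + overdispersion (when ``quasipoisson``),
    + autocorrelation (when ``autocorr_lags`` > 0). The conditional
    estimates are identical across formulations up to numerical error;
    ``max_abs_beta_diff`` makes that machine-checkable. An unconditional
    fit refused for exceeding the stratum cap is marked infeasible without
    failing the rest.
    """
    if index is None:
        index = build_index(series)
    if exposure is None:
        exposure = series.covariate_names[0]
    if exposure not in series.covariate_names:
        raise KeyError(f"exposure {exposure!r} not among covariates {series.covariate_names}")
    j = series.covariate_names.index(exposure)

    fits: dict[str, FitResult] = {}
    rows = []

    def row(label, fit, dispersion, note=""):
        if fit is None:
            return {
                "model": label, "pct_change": np.nan, "pct_lo95": np.nan,
                "pct_hi95": np.nan, "dispersion": np.nan, "n_params": np.nan,
                "note": note,
            }
        jj = fit.names.index(exposure)
        ci = fit.conf_int()[jj]
        return {
            "model": label,
            "pct_change": float(percent_change(fit.beta[jj], delta)),
            "pct_lo95": float(percent_change(ci[0], delta)),
            "pct_hi95": float(percent_change(ci[1], delta)),
            "dispersion": dispersion,
            "n_params": fit.n_params,
            "note": note,
        }

    clogit = fit_conditional_logistic(expand_casecrossover(series, index), options)
    fits["cond_logistic"] = clogit
    rows.append(row("conditional logistic", clogit, 1.0))

    try:
        uncond = fit_unconditional_poisson(series, index, stratum_cap=stratum_cap)
        fits["uncond_poisson"] = uncond
        rows.append(row("unconditional Poisson", uncond, 1.0))
    except StratumCapError as exc:
        uncond = None
        rows.append(row("unconditional Poisson", None, None, note=str(exc)))

    cond = fit_conditional_poisson(series, index, options)
    fits["cond_poisson"] = cond
    rows.append(row("conditional Poisson", cond, 1.0))

    if quasipoisson:
        psi = estimate_dispersion(cond, series, index)
        quasi = cond.with_dispersion(psi)
        fits["cond_poisson_quasi"] = quasi
        rows.append(row("+ overdispersion", quasi, psi))

    if autocorr_lags and autocorr_lags > 0:
        ac = fit_autocorr_adjusted(
            series, index, n_lags=autocorr_lags, options=options, base_fit=cond
        )
        fits["cond_poisson_autocorr"] = ac.adjusted
        rows.append(row("+ auto-correlation", ac.adjusted, 1.0))

    conds = [f for k, f in fits.items() if k in ("cond_logistic", "uncond_poisson", "cond_poisson")]
    diffs = [
        float(np.max(np.abs(a.beta - b.beta)))
        for i, a in enumerate(conds)
        for b in conds[i + 1:]
    ]
    table = pd.DataFrame(rows)
    return ModelComparison(
        table=table,
        fits=fits,
        max_abs_beta_diff=max(diffs) if diffs else 0.0,
    )
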
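"""Conditional Poisson maximum likelihood with quasi-Poisson dispersion.

The model: daily counts Y_i are Poisson with log-mean

    log mu_i = alpha_s(i) + x_i beta + offset_i,

where alpha_s is a per-stratum baseline. Conditioning on the stratum event
totals n_s = sum_{i in s} Y_i eliminates the alpha_s entirely and turns each
stratum into a multinomial: given n_s, the events fall on the stratum's days
with probabilities p_i proportional to exp(x_i beta + offset_i). The
conditional log-likelihood (multinomial coefficient omitted — it does not
involve beta) is

    l(beta) = sum_{s: n_s>0} [ sum_{i in s} Y_i eta_i  -  n_s log sum_{j in s} exp(eta_j) ].

Strata with n_s = 0 contribute exactly zero and are dropped. The likelihood
is concave; we maximize by Newton-Raphson with analytic gradient and Hessian
and step-halving, with per-stratum log-sum-exp stabilization.

Overdispersion psi is estimated from the Pearson chi-squared statistic over
the residual degrees of freedom; quasi-Poisson inference multiplies the
coefficient covariance by psi and leaves point estimates untouched.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import StratifiedSeries, StratumIndex, build_index
from .errors import ConvergenceError, DataError, NonIdentifiableError

__all__ = [
    "FitResult",
    "FitOptions",
    "conditional_loglik",
    "fit_conditional_poisson",
    "estimate_dispersion",
    "fitted_means",
    "percent_change",
]

# two-sided 95% normal quantile
Z95 = 1.959964


@dataclass(frozen=True)
class FitOptions:
    """Newton-Raphson controls for the conditional fitter.

    ``ll_rtol`` and ``grad_tol`` must both be satisfied to declare
    convergence; ``beta_max`` bounds the coefficient norm — crossing it is
    treated as divergence (complete or quasi-separation has no finite MLE).
    """

    max_iter: int = 50
    ll_rtol: float = 1e-9
    grad_tol: float = 1e-6
    max_halvings: int = 30
    beta_max: float = 25.0


@dataclass(eq=False)
class FitResult:
    """Fitted coefficients and inference for one model.

    ``beta`` holds log-rate-ratio coefficients (one per covariate; the
    autocorrelation adjustment appends a lagged-residual term). ``cov`` is
    the coefficient covariance; ``dispersion`` is psi when quasi-Poisson
    scaling has been applied (None otherwise). ``n_params`` counts reported
    coefficients, plus stratum baseline terms for the unconditional model.
    """

    beta: np.ndarray
    names: list[str]
    cov: np.ndarray
    loglik: float
    n_params: int
    converged: bool
    n_iter: int
    model_kind: str
    dispersion: float | None = None

    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2) if level != 0.95 else Z95
        se = self.se()
        return np.column_stack([self.beta - z * se, self.beta + z * se])

    def with_dispersion(self, psi: float) -> "FitResult":
        """Quasi-Poisson rescaling: covariance × psi, point estimates unchanged."""
        return dataclasses.replace(self, cov=self.cov * psi, dispersion=psi)

    def summary_frame(self) -> pd.DataFrame:
        se = self.se()
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, self.beta / se, np.nan)
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "term": self.names,
                "estimate": self.beta,
                "se": se,
                "z": z,
                "lo95": ci[:, 0],
                "hi95": ci[:, 1],
            }
        )

    def to_dict(self) -> dict:
        return {
            "model_kind": self.model_kind,
            "terms": self.names,
            "beta": self.beta.tolist(),
            "cov": self.cov.tolist(),
            "loglik": self.loglik,
            "dispersion": self.dispersion,
            "n_params": self.n_params,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


class _Grouped:
    """Active-stratum design flattened into contiguous groups."""

    def __init__(self, series: StratifiedSeries, index: StratumIndex):
        labels = index.active_labels
        self.labels = labels
        if labels:
            self.idx = np.concatenate([index.members[s] for s in labels])
        else:
            self.idx = np.zeros(0, dtype=np.intp)
        sizes = np.array([len(index.members[s]) for s in labels], dtype=np.intp)
        self.sizes = sizes
        self.starts = np.concatenate([[0], np.cumsum(sizes)[:-1]]).astype(np.intp)
        self.group_of = np.repeat(np.arange(len(labels)), sizes)
        self.y = series.counts[self.idx].astype(float)
        self.X = series.covariate_matrix[self.idx]
        self.off = series.offsets[self.idx]
        self.ns = np.array([index.totals[s] for s in labels], dtype=float)
        self.n_records = len(self.idx)

    def eta(self, beta: np.ndarray) -> np.ndarray:
        return self.X @ beta + self.off

    def probs(self, beta: np.ndarray) -> np.ndarray:
        """Within-stratum multinomial probabilities, log-sum-exp stabilized."""
        eta = self.eta(beta)
        if eta.size and not np.all(np.isfinite(eta)):
            bad = int(self.idx[np.flatnonzero(~np.isfinite(eta))[0]])
            raise DataError(f"non-finite linear predictor at record {bad}")
        m = np.maximum.reduceat(eta, self.starts) if eta.size else np.zeros(0)
        z = np.exp(eta - m[self.group_of])
        Z = np.add.reduceat(z, self.starts) if z.size else np.zeros(0)
        return z / Z[self.group_of], eta, m + np.log(Z, where=Z > 0, out=np.zeros_like(Z))

    def loglik(self, beta: np.ndarray) -> float:
        if self.n_records == 0:
            return 0.0
        _, eta, lse = self.probs(beta)
        return float(self.y @ eta - self.ns @ lse)

    def score_info(self, beta: np.ndarray):
        """Log-likelihood, gradient, and negative Hessian (information)."""
        if self.n_records == 0:
            p = len(beta)
            return 0.0, np.zeros(p), np.zeros((p, p))
        probs, eta, lse = self.probs(beta)
        mu = self.ns[self.group_of] * probs
        ll = float(self.y @ eta - self.ns @ lse)
        grad = self.X.T @ (self.y - mu)
        xbar = np.empty((len(self.labels), self.X.shape[1]))
        weighted = probs[:, None] * self.X
        np.add.reduceat(weighted, self.starts, axis=0, out=xbar)
        info = self.X.T @ (mu[:, None] * self.X) - xbar.T @ (self.ns[:, None] * xbar)
        return ll, grad, info


def _check_identifiable(g: _Grouped, names: Sequence[str]) -> None:
    """The design must have full rank after within-stratum centering."""
    if g.X.shape[1] == 0:
        raise NonIdentifiableError("no covariates to fit")
    if g.n_records == 0:
        raise DataError("no active strata (every stratum has zero events)")
    means = np.add.reduceat(g.X, g.starts, axis=0) / g.sizes[:, None]
    centered = g.X - means[g.group_of]
    p = centered.shape[1]
    sv = np.linalg.svd(centered, compute_uv=False)
    tol = max(centered.shape) * (sv[0] if sv.size else 0.0) * np.finfo(float).eps
    rank = int(np.sum(sv > max(tol, 1e-12)))
    if rank < p:
        norms = np.linalg.norm(centered, axis=0)
        scale = np.max(norms) if np.max(norms) > 0 else 1.0
        aliased = [str(names[j]) for j in range(p) if norms[j] <= 1e-10 * max(scale, 1.0)]
        if not aliased:
            aliased = [str(n) for n in names]
        raise NonIdentifiableError(
            "covariate(s) constant within every active stratum or collinear "
            f"after within-stratum centering: {aliased}",
            aliased=aliased,
        )


def conditional_loglik(
    beta: np.ndarray, series: StratifiedSeries, index: StratumIndex | None = None
) -> float:
    """Conditional (multinomial) log-likelihood at ``beta``.

    Inactive strata contribute exactly zero; the multinomial combinatorial
    constant is omitted throughout (it does not depend on beta).
    """
    if index is None:
        index = build_index(series)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    if beta.shape != (series.covariates.shape[1],):
        raise DataError(
            f"beta has shape {beta.shape}, expected ({series.covariates.shape[1]},)"
        )
    return _Grouped(series, index).loglik(beta)


def _newton(g: _Grouped, names: Sequence[str], options: FitOptions):
    p = g.X.shape[1]
    beta = np.zeros(p)
    ll, grad, info = g.score_info(beta)
    trace = [ll]
    converged = False
    it = 0
    for it in range(1, options.max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        # step-halving: accept only steps that do not decrease the loglik
        accepted = False
        for h in range(options.max_halvings + 1):
            cand = beta + step / (2**h)
            ll_new = g.loglik(cand)
            if ll_new >= ll - 1e-13 * max(1.0, abs(ll)):
                accepted = True
                break
        if not accepted:
            raise ConvergenceError(
                "Newton step failed to improve the conditional log-likelihood "
                f"after {options.max_halvings} halvings (iteration {it})",
                trace=trace,
            )
        rel = abs(ll_new - ll) / max(1.0, abs(ll))
        beta, ll = cand, ll_new
        trace.append(ll)
        if np.max(np.abs(beta)) > options.beta_max:
            raise ConvergenceError(
                "coefficients diverged (|beta| exceeded "
                f"{options.beta_max}); the conditional MLE is likely infinite "
                "(complete or quasi-separation)",
                trace=trace,
            )
        ll, grad, info = g.score_info(beta)
        if rel < options.ll_rtol and np.max(np.abs(grad)) < options.grad_tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"no convergence after {options.max_iter} Newton iterations", trace=trace
        )
    # a (quasi-)separated likelihood flattens out: the gradient criterion is
    # met while the curvature collapses relative to its value at beta = 0,
    # where the information is full rank by the identifiability check
    _, _, info0 = g.score_info(np.zeros(p))
    eig_hat = float(np.min(np.linalg.eigvalsh(info)))
    eig_0 = float(np.min(np.linalg.eigvalsh(info0)))
    if eig_0 > 0 and eig_hat < 1e-4 * eig_0:
        raise ConvergenceError(
            "information matrix collapsed at the optimum (curvature "
            f"{eig_hat:.3g} vs {eig_0:.3g} at beta = 0); the MLE is likely "
            "infinite (complete or quasi-separation)",
            trace=trace,
        )
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    cov = (cov + cov.T) / 2
    return beta, cov, ll, it


def fit_conditional_poisson(
    series: StratifiedSeries,
    index: StratumIndex | None = None,
    options: FitOptions | None = None,
) -> FitResult:
    """Maximize the conditional Poisson (multinomial) likelihood.

    Newton-Raphson from beta = 0 with analytic gradient and Hessian and
    step-halving. The covariance is the inverse observed information at the
    maximum; 95% Wald intervals follow from :meth:`FitResult.conf_int`.

    Raises
    ------
    NonIdentifiableError
        if every covariate is constant within every active stratum (or the
        centered design is otherwise rank deficient).
    ConvergenceError
        on divergence (no finite MLE) or iteration exhaustion.
    """
    if index is None:
        index = build_index(series)
    options = options or FitOptions()
    g = _Grouped(series, index)
    names = series.covariate_names
    _check_identifiable(g, names)
    beta, cov, ll, it = _newton(g, names, options)
    return FitResult(
        beta=beta,
        names=names,
        cov=cov,
        loglik=ll,
        n_params=len(beta),
        converged=True,
        n_iter=it,
        model_kind="cond_poisson",
    )


def fitted_means(
    fit: FitResult, series: StratifiedSeries, index: StratumIndex | None = None
) -> np.ndarray:
    """Per-record fitted means mu_i = n_s * p_i (NaN on inactive strata).

    Within each active stratum the fitted means sum exactly to the stratum
    total n_s — the multinomial normalization.
    """
    if index is None:
        index = build_index(series)
    g = _Grouped(series, index)
    mu = np.full(series.n_records, np.nan)
    if g.n_records:
        probs, _, _ = g.probs(fit.beta[: g.X.shape[1]])
        mu[g.idx] = g.ns[g.group_of] * probs
    return mu


def estimate_dispersion(
    fit: FitResult,
    series: StratifiedSeries,
    index: StratumIndex | None = None,
    sparse_warn_threshold: float = 5.0,
) -> float:
    """Pearson-based overdispersion psi.

    psi = [sum over active-stratum records of (Y_i - mu_i)^2 / mu_i] / df
    with df = (records in active strata) - (active strata) - len(beta):
    the stratum baselines eliminated by conditioning still consume degrees
    of freedom, exactly as in the equivalent unconditional model.

    Pearson-based psi is not consistent when events per stratum are sparse;
    a warning is emitted when the mean events per active stratum falls
    below ``sparse_warn_threshold``.
    """
    if index is None:
        index = build_index(series)
    g = _Grouped(series, index)
    n_active_records = g.n_records
    n_active_strata = len(g.labels)
    df = n_active_records - n_active_strata - len(fit.beta)
    if df <= 0:
        raise DataError(
            f"non-positive residual degrees of freedom (df = {df}); "
            "dispersion is not estimable"
        )
    if n_active_strata and g.ns.mean() < sparse_warn_threshold:
        warnings.warn(
            f"mean events per active stratum is {g.ns.mean():.2f} (< "
            f"{sparse_warn_threshold}); the Pearson dispersion estimate is "
            "unreliable for sparse data",
            stacklevel=2,
        )
    probs, _, _ = g.probs(fit.beta)
    mu = g.ns[g.group_of] * probs
    pearson = float(np.sum((g.y - mu) ** 2 / mu))
    return pearson / df


def percent_change(beta_k: float, delta: float = 1.0):
    """Percent change in the rate per ``delta`` units of exposure.

    100 * (exp(delta * beta) - 1) — the conventional reporting scale for
    air-pollution coefficients (e.g. per 10 ug/m3). Apply the same
    transform to CI bounds. Accepts scalars or arrays.
    """
    return 100.0 * np.expm1(np.asarray(beta_k, dtype=float) * delta)
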
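"""The two formulations equivalent to the conditional Poisson model.

Time-stratified case-crossover data are conventionally analysed by
conditional logistic regression on an expanded case-control layout: every
day with at least one event becomes a matched set in which that day is the
"case" and all other days of the same calendar stratum are "controls". With
multiple events per day the expansion is kept "semi-expanded" by weighting
each set by the case day's event count instead of repeating it.

Both that model and an ordinary (unconditional) Poisson regression with one
indicator per stratum yield identical covariate estimates and standard
errors to the conditional Poisson fit — they maximize the same profile
likelihood. They are provided here both for completeness and as mutual
cross-checks; the unconditional variant is practical only while the stratum
count is modest (its information matrix grows with the square of the number
of strata), and refuses designs above a configurable cap.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .condfit import FitOptions, FitResult
from .data_model import StratifiedSeries, StratumIndex, build_index
from .errors import ConvergenceError, DataError, StratumCapError

__all__ = [
    "expand_casecrossover",
    "collapse_expansion",
    "fit_conditional_logistic",
    "fit_unconditional_poisson",
]

EXPANSION_META_COLS = ("stratum", "set_id", "date", "case_flag", "weight")


def expand_casecrossover(
    series: StratifiedSeries, index: StratumIndex | None = None
) -> pd.DataFrame:
    """Semi-expanded case-crossover layout.

    For every record with Y_i > 0, emit one case-control set: that day
    flagged as the case, every day of the same stratum as a row, and the
    whole set weighted by Y_i. Row order is deterministic: stratum (first
    appearance), case day (record order), member day (record order).

    One-day strata still appear (a 1-row set) but contribute nothing to the
    conditional-logistic likelihood.
    """
    if index is None:
        index = build_index(series)
    frames = []
    for s in index.labels:
        members = index.members[s]
        case_rows = [i for i in members if series.counts[i] > 0]
        for k, i in enumerate(case_rows, start=1):
            frames.append(
                pd.DataFrame(
                    {
                        "stratum": s,
                        "set_id": f"{s}.{k}",
                        "date": series.dates[members],
                        **{
                            c: series.covariates[c].to_numpy()[members]
                            for c in series.covariates.columns
                        },
                        "case_flag": (members == i).astype(int),
                        "weight": int(series.counts[i]),
                    }
                )
            )
    if not frames:
        cols = list(EXPANSION_META_COLS[:3]) + series.covariate_names + list(
            EXPANSION_META_COLS[3:]
        )
        return pd.DataFrame(columns=cols)
    out = pd.concat(frames, ignore_index=True)
    ordered = ["stratum", "set_id", "date", *series.covariate_names, "case_flag", "weight"]
    return out[ordered]


def collapse_expansion(rows: pd.DataFrame) -> pd.DataFrame:
    """Recover per-day counts from an expansion (days with events only).

    The case row of each set carries the day's count as its weight, so
    grouping case rows by date and taking the weight inverts the expansion.
    """
    cases = rows[rows["case_flag"] == 1]
    out = cases.groupby("date", sort=True)["weight"].first().reset_index()
    return out.rename(columns={"weight": "count"})


def _expansion_covariate_names(rows: pd.DataFrame) -> list[str]:
    return [c for c in rows.columns if c not in EXPANSION_META_COLS]


def fit_conditional_logistic(
    rows: pd.DataFrame, options: FitOptions | None = None
) -> FitResult:
    """Weighted conditional logistic fit on semi-expanded data.

    Maximizes sum over sets of weight * [eta_case - log sum_set exp(eta)]
    — the matched-set likelihood with each set weighted by its case day's
    event count. This is fitted directly from the expanded rows (damped
    Newton iteration on the set-grouped objective with analytic
    derivatives), independently of the stratified-count fitter, although
    the two objectives coincide mathematically.
    """
    options = options or FitOptions()
    names = _expansion_covariate_names(rows)
    if not names:
        raise DataError("expansion carries no covariate columns")
    X = rows[names].to_numpy(dtype=float)

    set_codes, set_order = pd.factorize(rows["set_id"], sort=False)
    n_sets = len(set_order)
    case = rows["case_flag"].to_numpy(dtype=int)
    for sid in range(n_sets):
        n_cases = int(case[set_codes == sid].sum())
        if n_cases != 1:
            raise DataError(
                f"set {set_order[sid]!r} has {n_cases} case rows (expected exactly 1)"
            )
    w_set = np.zeros(n_sets)
    w_set[set_codes[case == 1]] = rows.loc[rows["case_flag"] == 1, "weight"].to_numpy(float)
    case_x = np.zeros((n_sets, X.shape[1]))
    case_x[set_codes[case == 1]] = X[case == 1]

    def objective(beta):
        eta = X @ beta
        m = np.full(n_sets, -np.inf)
        np.maximum.at(m, set_codes, eta)
        z = np.exp(eta - m[set_codes])
        Z = np.zeros(n_sets)
        np.add.at(Z, set_codes, z)
        lse = m + np.log(Z)
        p = z / Z[set_codes]
        eta_case = eta[case == 1][np.argsort(set_codes[case == 1])]
        # sets are factorized in order of appearance so set_codes of case
        # rows are already 0..n_sets-1 in order; the argsort is a no-op kept
        # for safety with arbitrary row orderings
        nll = -float(w_set @ (eta_case - lse))
        xbar = np.zeros((n_sets, X.shape[1]))
        np.add.at(xbar, set_codes, p[:, None] * X)
        grad = -(w_set[:, None] * (case_x - xbar)).sum(axis=0)
        wrow = w_set[set_codes] * p
        hess = X.T @ (wrow[:, None] * X) - xbar.T @ (w_set[:, None] * xbar)
        return nll, grad, hess

    p_dim = X.shape[1]
    # gradient components scale with the total set weight and covariate
    # magnitude; tolerance is taken relative to that scale
    gscale = max(1.0, float(w_set.sum()) * max(1.0, float(np.max(np.abs(X), initial=0.0))))
    beta = np.zeros(p_dim)
    nll, grad, hess = objective(beta)
    trace = [-nll]
    converged = False
    n_iter = 0
    for n_iter in range(1, options.max_iter + 1):
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, -grad, rcond=None)[0]
        accepted = False
        for h in range(options.max_halvings + 1):
            cand = beta + step / (2**h)
            nll_new = objective(cand)[0]
            if nll_new <= nll + 1e-13 * max(1.0, abs(nll)):
                accepted = True
                break
        if not accepted:
            raise ConvergenceError(
                "conditional logistic Newton step failed to improve the "
                f"likelihood (iteration {n_iter})",
                trace=trace,
            )
        rel = abs(nll_new - nll) / max(1.0, abs(nll))
        beta = cand
        nll, grad, hess = objective(beta)
        trace.append(-nll)
        if np.max(np.abs(beta)) > options.beta_max:
            raise ConvergenceError(
                "conditional logistic coefficients diverged (no finite MLE — "
                "complete separation of the matched sets)",
                trace=trace,
            )
        if rel < options.ll_rtol and np.max(np.abs(grad)) < options.grad_tol * gscale:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"conditional logistic fit did not converge in {options.max_iter} "
            "iterations",
            trace=trace,
        )
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        raise ConvergenceError(
            "singular information matrix at the conditional logistic optimum"
        )
    cov = (cov + cov.T) / 2
    if np.any(np.diag(cov) <= 0) or np.any(np.diag(cov) > 1e8):
        raise ConvergenceError(
            "conditional logistic information is numerically singular "
            "(likely separation: a single event cannot identify a finite MLE)"
        )
    return FitResult(
        beta=beta,
        names=names,
        cov=cov,
        loglik=-nll,
        n_params=p_dim,
        converged=True,
        n_iter=n_iter,
        model_kind="cond_logistic",
    )


def fit_unconditional_poisson(
    series: StratifiedSeries,
    index: StratumIndex | None = None,
    stratum_cap: int = 2000,
) -> FitResult:
    """Ordinary Poisson regression with one indicator per active stratum.

    Fitted by IRLS (statsmodels GLM) on active-stratum records only, with
    an intercept, S-1 stratum indicators, and the covariates; only the
    covariate coefficients are reported in ``beta``, while ``n_params``
    counts the covariates plus the S-1 stratum indicators (the convention
    used when contrasting against the 2-coefficient conditional fits).

    Designs with more active strata than ``stratum_cap`` are refused: the
    IRLS step inverts a matrix of order S, which is exactly the burden the
    conditional fitter exists to avoid.
    """
    if index is None:
        index = build_index(series)
    labels = index.active_labels
    S = len(labels)
    if S == 0:
        raise DataError("no active strata (every stratum has zero events)")
    if S > stratum_cap:
        raise StratumCapError(
            f"{S} active strata exceed the cap of {stratum_cap} for the dense "
            "unconditional fitter; use fit_conditional_poisson instead"
        )
    keep = np.concatenate([index.members[s] for s in labels])
    keep = np.sort(keep)
    y = series.counts[keep].astype(float)
    Xc = series.covariate_matrix[keep]
    off = series.offsets[keep]
    strata = pd.Categorical(series.strata[keep], categories=labels)
    dummies = pd.get_dummies(strata, drop_first=True, dtype=float).to_numpy()
    design = np.column_stack([np.ones(len(keep)), dummies, Xc])
    names = series.covariate_names

    model = sm.GLM(y, design, family=sm.families.Poisson(), offset=off)
    try:
        res = model.fit(maxiter=300, tol=1e-12)
    except Exception as exc:  # statsmodels raises bare errors on failure
        raise ConvergenceError(f"unconditional Poisson IRLS failed: {exc}") from exc
    if not np.all(np.isfinite(res.params)):
        raise ConvergenceError("unconditional Poisson IRLS produced non-finite coefficients")
    p = Xc.shape[1]
    sl = slice(design.shape[1] - p, design.shape[1])
    beta = np.asarray(res.params[sl])
    cov = np.asarray(res.cov_params())[sl, sl]
    cov = (cov + cov.T) / 2
    return FitResult(
        beta=beta,
        names=names,
        cov=cov,
        loglik=float(res.llf),
        n_params=p + (S - 1),
        converged=bool(res.converged),
        n_iter=int(getattr(res, "fit_history", {}).get("iteration", 0) or 0),
        model_kind="uncond_poisson",
    )
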
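import numpy as np
import pandas as pd
import pytest
import scipy.optimize

from condpoisson import (
    ConvergenceError,
    DataError,
    NonIdentifiableError,
    StratifiedSeries,
    build_index,
    conditional_loglik,
    estimate_dispersion,
    fit_conditional_poisson,
    fitted_means,
    percent_change,
)
from condpoisson.condfit import _Grouped

from conftest import random_small_series


def _one_stratum(counts, x):
    n = len(counts)
    return StratifiedSeries.from_arrays(
        pd.date_range("2005-06-01", periods=n, freq="D"),
        counts,
        pd.DataFrame({"x": x}),
        strata=["s"] * n,
    )


class TestConditionalLoglik:
    def test_uniform_multinomial(self):
        # one event over two equally likely days
        s = _one_stratum([1, 0], [0.0, 1.0])
        assert conditional_loglik([0.0], s) == pytest.approx(-np.log(2), abs=1e-12)

    def test_single_event_probability(self):
        # P(event on day 2) = e^beta / (1 + e^beta) = 3/4 at beta = log 3
        s = _one_stratum([0, 1], [0.0, 1.0])
        assert conditional_loglik([np.log(3)], s) == pytest.approx(np.log(3 / 4), abs=1e-12)

    def test_all_inactive_strata_contribute_zero(self):
        s = _one_stratum([0, 0, 0], [0.0, 1.0, 2.0])
        assert conditional_loglik([1.3], s) == 0.0

    def test_beta_shape_checked(self):
        s = _one_stratum([1, 0], [0.0, 1.0])
        with pytest.raises(DataError, match="shape"):
            conditional_loglik([0.0, 1.0], s)

    def test_stratum_shift_invariance(self, two_strata_toy, toy_index):
        """Adding a per-stratum constant to the linear predictor (via the
        offset) must not change the likelihood — the elimination property."""
        shifts = {"a": 3.7, "b": -12.0}
        shifted = StratifiedSeries.from_arrays(
            two_strata_toy.dates,
            two_strata_toy.counts,
            two_strata_toy.covariates,
            offsets=np.array([shifts[s] for s in two_strata_toy.strata]),
            strata=two_strata_toy.strata,
        )
        for beta in ([0.0], [0.5], [-1.7]):
            assert conditional_loglik(beta, shifted) == pytest.approx(
                conditional_loglik(beta, two_strata_toy), abs=1e-9
            )
        f1 = fit_conditional_poisson(two_strata_toy)
        f2 = fit_conditional_poisson(shifted)
        np.testing.assert_allclose(f1.beta, f2.beta, atol=1e-8)


class TestFitConditionalPoisson:
    def test_single_stratum_closed_form(self):
        s = _one_stratum([3, 6], [0.0, 1.0])
        fit = fit_conditional_poisson(s)
        assert fit.beta[0] == pytest.approx(np.log(2), abs=1e-9)
        assert fit.converged

    def test_two_strata_matches_grid_oracle(self, two_strata_toy, toy_index):
        fit = fit_conditional_poisson(two_strata_toy, toy_index)
        res = scipy.optimize.minimize_scalar(
            lambda b: -conditional_loglik([b], two_strata_toy, toy_index),
            bounds=(-5, 5), method="bounded", options={"xatol": 1e-10},
        )
        assert fit.beta[0] == pytest.approx(res.x, abs=1e-6)

    def test_random_instances_match_derivative_free_oracle(self):
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 25:
            s = random_small_series(rng)
            try:
                fit = fit_conditional_poisson(s)
            except (ConvergenceError, NonIdentifiableError):
                continue
            res = scipy.optimize.minimize(
                lambda b: -conditional_loglik(b, s),
                np.zeros(len(fit.beta)),
                method="Nelder-Mead",
                options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 5000},
            )
            np.testing.assert_allclose(fit.beta, res.x, atol=1e-5)
            checked += 1

    def test_constant_covariate_not_identifiable(self):
        s = StratifiedSeries.from_arrays(
            pd.date_range("2002-01-01", periods=4, freq="D"),
            [1, 2, 3, 4],
            pd.DataFrame({"x": [1.0, 1.0, 2.0, 2.0]}),
            strata=["a", "a", "b", "b"],
        )
        with pytest.raises(NonIdentifiableError) as exc:
            fit_conditional_poisson(s)
        assert "x" in exc.value.aliased

    def test_separation_raises_convergence_error(self):
        # a single event on the high-exposure day has no finite MLE
        s = _one_stratum([0, 1], [0.0, 1.0])
        with pytest.raises(ConvergenceError):
            fit_conditional_poisson(s)

    def test_fitted_means_sum_to_stratum_totals(self):
        rng = np.random.default_rng(11)
        while True:
            s = random_small_series(rng)
            idx = build_index(s)
            try:
                fit = fit_conditional_poisson(s, idx)
                break
            except (ConvergenceError, NonIdentifiableError):
                continue
        mu = fitted_means(fit, s, idx)
        for lbl in idx.active_labels:
            members = idx.members[lbl]
            assert np.nansum(mu[members]) == pytest.approx(idx.totals[lbl], rel=1e-9)

    def test_information_is_positive_semidefinite(self, two_strata_toy, toy_index):
        g = _Grouped(two_strata_toy, toy_index)
        rng = np.random.default_rng(0)
        for _ in range(20):
            beta = rng.normal(scale=2.0, size=1)
            _, _, info = g.score_info(beta)
            assert np.min(np.linalg.eigvalsh(info)) >= -1e-10


class TestDispersion:
    def test_exact_fit_gives_zero(self, exact_fit_series):
        idx = build_index(exact_fit_series)
        fit = fit_conditional_poisson(exact_fit_series, idx)
        with pytest.warns(UserWarning, match="sparse"):
            psi = estimate_dispersion(fit, exact_fit_series, idx)
        assert psi == pytest.approx(0.0, abs=1e-12)

    def test_df_nonpositive_rejected(self):
        s = _one_stratum([3, 6], [0.0, 1.0])
        fit = fit_conditional_poisson(s)
        with pytest.raises(DataError, match="degrees of freedom"):
            estimate_dispersion(fit, s)

    def test_quasipoisson_rescaling_exact(self):
        rng = np.random.default_rng(5)
        s = random_small_series(rng)
        fit = fit_conditional_poisson(s)
        psi = 1.8342
        quasi = fit.with_dispersion(psi)
        np.testing.assert_array_equal(quasi.beta, fit.beta)
        np.testing.assert_allclose(quasi.se(), fit.se() * np.sqrt(psi), rtol=1e-12)
        assert quasi.dispersion == psi


class TestPercentChange:
    @pytest.mark.parametrize(
        "beta,delta,expected,tol",
        [
            (0.0, 10.0, 0.0, 1e-12),
            (np.log(1.05) / 10, 10.0, 5.0, 1e-9),
            (3.4e-4, 10.0, 0.340578, 1e-4),
        ],
    )
    def test_values(self, beta, delta, expected, tol):
        assert percent_change(beta, delta) == pytest.approx(expected, abs=tol)

    def test_vectorized(self):
        out = percent_change(np.array([0.0, np.log(2)]), 1.0)
        np.testing.assert_allclose(out, [0.0, 100.0])
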
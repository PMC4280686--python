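import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import gammaln

from condpoisson import (
    ConvergenceError,
    DataError,
    NonIdentifiableError,
    StratifiedSeries,
    StratumCapError,
    build_index,
    collapse_expansion,
    expand_casecrossover,
    fit_conditional_logistic,
    fit_conditional_poisson,
    fit_unconditional_poisson,
)

from conftest import random_small_series


class TestExpansion:
    def test_one_stratum_semi_expanded_layout(self, january_sundays):
        """Four Sundays with deaths on every day yield 4 sets x 4 rows, each
        set weighted by its case day's count with the case flag on that day."""
        rows = expand_casecrossover(january_sundays)
        assert len(rows) == 16
        assert rows["set_id"].nunique() == 4
        weights = rows.groupby("set_id", sort=False)["weight"].unique()
        assert [w.item() for w in weights] == [198, 204, 167, 169]
        # set 1: case on 06 jan; set 3: case on 20 jan
        set1 = rows[rows["set_id"] == "2002-01-Sun.1"]
        assert set1.loc[set1["case_flag"] == 1, "date"].dt.day.item() == 6
        set3 = rows[rows["set_id"] == "2002-01-Sun.3"]
        assert set3.loc[set3["case_flag"] == 1, "date"].dt.day.item() == 20
        assert (set3["weight"] == 167).all()
        # every set has exactly one case row and covariates copied verbatim
        assert (rows.groupby("set_id")["case_flag"].sum() == 1).all()
        assert rows["ozone"].tolist() == [2.4, 17.6, 49.9, 42.5] * 4

    def test_zero_count_stratum_emits_nothing(self):
        s = StratifiedSeries.from_arrays(
            ["2002-01-06", "2002-01-13"], [0, 0],
            pd.DataFrame({"x": [0.0, 1.0]}), strata=["a", "a"],
        )
        assert len(expand_casecrossover(s)) == 0

    def test_one_day_stratum_degenerate_set(self):
        s = StratifiedSeries.from_arrays(
            ["2002-01-06"], [5], pd.DataFrame({"x": [1.0]}), strata=["a"]
        )
        rows = expand_casecrossover(s)
        assert len(rows) == 1
        assert rows["weight"].item() == 5 and rows["case_flag"].item() == 1

    def test_conservation_and_roundtrip(self):
        rng = np.random.default_rng(21)
        s = random_small_series(rng)
        rows = expand_casecrossover(s)
        n_event_days = int((s.counts > 0).sum())
        assert rows["set_id"].nunique() == n_event_days
        case_rows = rows[rows["case_flag"] == 1]
        assert case_rows["weight"].sum() == s.counts.sum()
        collapsed = collapse_expansion(rows)
        original = (
            pd.DataFrame({"date": s.dates, "count": s.counts})
            .query("count > 0").sort_values("date").reset_index(drop=True)
        )
        pd.testing.assert_frame_equal(
            collapsed, original, check_dtype=False
        )


class TestConditionalLogistic:
    def test_matches_conditional_poisson(self, two_strata_toy, toy_index):
        rows = expand_casecrossover(two_strata_toy, toy_index)
        cl = fit_conditional_logistic(rows)
        cp = fit_conditional_poisson(two_strata_toy, toy_index)
        np.testing.assert_allclose(cl.beta, cp.beta, atol=1e-6)
        np.testing.assert_allclose(cl.se(), cp.se(), atol=1e-6)
        assert cl.loglik == pytest.approx(cp.loglik, abs=1e-8)
        assert cl.n_params == 1

    def test_single_event_separation(self):
        rows = pd.DataFrame(
            {
                "stratum": ["a", "a"],
                "set_id": ["a.1", "a.1"],
                "date": pd.to_datetime(["2002-01-06", "2002-01-13"]),
                "x": [0.0, 1.0],
                "case_flag": [0, 1],
                "weight": [1, 1],
            }
        )
        with pytest.raises(ConvergenceError):
            fit_conditional_logistic(rows)

    def test_set_without_case_rejected(self):
        rows = pd.DataFrame(
            {
                "stratum": ["a", "a"],
                "set_id": ["a.1", "a.1"],
                "date": pd.to_datetime(["2002-01-06", "2002-01-13"]),
                "x": [0.0, 1.0],
                "case_flag": [0, 0],
                "weight": [1, 1],
            }
        )
        with pytest.raises(DataError, match="case"):
            fit_conditional_logistic(rows)


class TestUnconditionalPoisson:
    def test_matches_conditional_poisson(self, two_strata_toy, toy_index):
        up = fit_unconditional_poisson(two_strata_toy, toy_index)
        cp = fit_conditional_poisson(two_strata_toy, toy_index)
        np.testing.assert_allclose(up.beta, cp.beta, atol=1e-6)
        np.testing.assert_allclose(up.se(), cp.se(), atol=1e-6)
        # p covariates + (S-1) stratum indicators
        assert up.n_params == 1 + (2 - 1)

    def test_loglik_differs_by_eliminated_terms_only(self, two_strata_toy, toy_index):
        """At the joint MLE the full Poisson log-likelihood equals the
        conditional one plus sum_s (n_s log n_s - n_s) - sum_i log Y_i!."""
        up = fit_unconditional_poisson(two_strata_toy, toy_index)
        cp = fit_conditional_poisson(two_strata_toy, toy_index)
        ns = np.array([toy_index.totals[s] for s in toy_index.active_labels], float)
        y = two_strata_toy.counts.astype(float)
        eliminated = np.sum(ns * np.log(ns) - ns) - np.sum(gammaln(y + 1))
        assert up.loglik == pytest.approx(cp.loglik + eliminated, abs=1e-6)

    def test_stratum_cap_refusal(self, two_strata_toy, toy_index):
        with pytest.raises(StratumCapError, match="conditional"):
            fit_unconditional_poisson(two_strata_toy, toy_index, stratum_cap=1)

    def test_single_stratum_is_plain_poisson(self):
        s = StratifiedSeries.from_arrays(
            pd.date_range("2002-01-01", periods=6, freq="D"),
            [3, 5, 2, 8, 4, 6],
            pd.DataFrame({"x": [0.1, 0.9, -0.3, 1.2, 0.0, 0.7]}),
            strata=["m"] * 6,
        )
        up = fit_unconditional_poisson(s)
        X = sm.add_constant(s.covariate_matrix)
        ref = sm.GLM(s.counts.astype(float), X, family=sm.families.Poisson()).fit()
        assert up.beta[0] == pytest.approx(ref.params[1], abs=1e-8)
        assert up.n_params == 1  # one covariate, no extra stratum indicators


class TestThreeWayEquivalence:
    def test_randomized_small_datasets(self):
        """Conditional Poisson, unconditional Poisson and conditional
        logistic maximize the same profile likelihood, so estimates and
        standard errors coincide."""
        rng = np.random.default_rng(100)
        checked = 0
        while checked < 20:
            s = random_small_series(rng)
            idx = build_index(s)
            try:
                cp = fit_conditional_poisson(s, idx)
                cl = fit_conditional_logistic(expand_casecrossover(s, idx))
                up = fit_unconditional_poisson(s, idx)
            except (ConvergenceError, NonIdentifiableError):
                continue
            np.testing.assert_allclose(cp.beta, cl.beta, atol=1e-5)
            np.testing.assert_allclose(cp.beta, up.beta, atol=1e-5)
            np.testing.assert_allclose(cp.se(), cl.se(), atol=1e-5)
            np.testing.assert_allclose(cp.se(), up.se(), atol=1e-5)
            checked += 1
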
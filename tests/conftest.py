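import numpy as np
import pandas as pd
import pytest

from condpoisson import StratifiedSeries, build_index


@pytest.fixture
def january_sundays():
    """Four consecutive Sundays of January 2002 with ozone, temperature and
    all-cause death counts — one complete year x month x day-of-week stratum."""
    return StratifiedSeries.from_arrays(
        dates=["2002-01-06", "2002-01-13", "2002-01-20", "2002-01-27"],
        counts=[198, 204, 167, 169],
        covariates=pd.DataFrame(
            {"ozone": [2.4, 17.6, 49.9, 42.5], "temperature": [7.1, 8.2, 8.9, 10.5]}
        ),
        scheme="year_month_dow",
    )


@pytest.fixture
def two_strata_toy():
    """Two strata, each two days with binary covariate x = (0, 1); counts
    (2, 1) and (4, 2), so the within-stratum rate ratio is 1/2 in both."""
    return StratifiedSeries.from_arrays(
        dates=pd.date_range("2002-01-01", periods=4, freq="7D"),
        counts=[2, 1, 4, 2],
        covariates=pd.DataFrame({"x": [0.0, 1.0, 0.0, 1.0]}),
        strata=["a", "a", "b", "b"],
    )


@pytest.fixture
def exact_fit_series():
    """Two binary-covariate strata whose counts the conditional model fits
    exactly (both within-stratum ratios equal 2), leaving one residual df."""
    return StratifiedSeries.from_arrays(
        dates=pd.date_range("2003-03-01", periods=4, freq="D"),
        counts=[2, 4, 1, 2],
        covariates=pd.DataFrame({"x": [0.0, 1.0, 0.0, 1.0]}),
        strata=["s1", "s1", "s2", "s2"],
    )


def random_small_series(rng: np.random.Generator) -> StratifiedSeries:
    """A random small stratified dataset: 2-6 strata of 2-7 days, 1-2
    continuous covariates, integer counts in 0..20."""
    n_strata = int(rng.integers(2, 7))
    n_cov = int(rng.integers(1, 3))
    sizes = rng.integers(2, 8, size=n_strata)
    n = int(sizes.sum())
    x = rng.normal(size=(n, n_cov))
    counts = rng.integers(0, 21, size=n)
    strata = np.repeat([f"s{j}" for j in range(n_strata)], sizes)
    dates = pd.date_range("2010-01-01", periods=n, freq="D")
    cov = pd.DataFrame(x, columns=[f"x{j + 1}" for j in range(n_cov)])
    return StratifiedSeries.from_arrays(dates, counts, cov, strata=strata)


@pytest.fixture
def toy_index(two_strata_toy):
    return build_index(two_strata_toy)
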
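"""Stratified count time series: containers, time strata, readers.

The central object is :class:`StratifiedSeries` — one record per time unit
(typically a day) holding an event count ``Y_i``, a numeric covariate vector
``x_i``, an optional log-offset, and a stratum label ``s``. Time strata are
the calendar cells of the time-stratified case-crossover design: all days
sharing (year, month) or (year, month, day-of-week) form one stratum, and
underlying risk is assumed constant within it.

:class:`StratumIndex` maps each stratum to its member records and its total
event count ``n_s``; strata with ``n_s = 0`` contribute nothing to the
conditional likelihood and are flagged inactive.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "StratifiedSeries",
    "StratumIndex",
    "make_strata",
    "build_index",
    "read_series",
    "SCHEMES",
]

SCHEMES = ("year_month_dow", "year_month")

# English three-letter weekday abbreviations, Monday-indexed to match
# pandas' dayofweek (proleptic Gregorian calendar).
_WEEKDAY_ABBR = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")


def _coerce_dates(dates) -> pd.DatetimeIndex:
    """Parse anything date-like into a DatetimeIndex, naming offenders."""
    if isinstance(dates, pd.DatetimeIndex):
        return dates
    arr = pd.Index(dates)
    parsed = pd.to_datetime(arr, errors="coerce", format="ISO8601" if arr.dtype == object else None)
    if parsed.isna().any():
        bad = int(np.flatnonzero(parsed.isna())[0])
        raise DataError(f"unparseable date at record {bad}: {arr[bad]!r}")
    return pd.DatetimeIndex(parsed)


def make_strata(dates, scheme: str = "year_month_dow") -> np.ndarray:
    """Assign each date to its calendar stratum.

    Parameters
    ----------
    dates
        Calendar dates (anything :func:`pandas.to_datetime` accepts).
    scheme
        ``"year_month_dow"`` — strata are day-of-week within month
        (label ``YYYY-MM-Ddd``, e.g. ``2002-01-Sun``); ``"year_month"`` —
        strata are months (label ``YYYY-MM``).

    Returns
    -------
    numpy.ndarray of str
        One label per input date. The label is a deterministic function of
        the calendar tuple, so the mapping is idempotent and
        order-independent.
    """
    if scheme not in SCHEMES:
        raise DataError(f"unknown stratification scheme {scheme!r}; choose from {SCHEMES}")
    idx = _coerce_dates(dates)
    ym = [f"{y:04d}-{m:02d}" for y, m in zip(idx.year, idx.month)]
    if scheme == "year_month":
        return np.asarray(ym, dtype=object)
    return np.asarray(
        [f"{base}-{_WEEKDAY_ABBR[d]}" for base, d in zip(ym, idx.dayofweek)],
        dtype=object,
    )


@dataclass(eq=False)
class StratifiedSeries:
    """One record per time unit: date, event count, covariates, offset, stratum.

    Invariants enforced at construction: counts are non-negative integers,
    covariates contain no missing values (missingness is a hard error — a
    silently dropped day would corrupt its stratum), and every record
    carries a stratum label.
    """

    dates: pd.DatetimeIndex
    counts: np.ndarray
    covariates: pd.DataFrame
    offsets: np.ndarray
    strata: np.ndarray

    def __post_init__(self) -> None:
        self.dates = _coerce_dates(self.dates)
        n = len(self.dates)

        counts = np.asarray(self.counts)
        if counts.shape != (n,):
            raise DataError(f"counts has shape {counts.shape}, expected ({n},)")
        if not np.issubdtype(counts.dtype, np.integer):
            flt = counts.astype(float)
            if not np.all(np.isfinite(flt)) or np.any(flt != np.round(flt)):
                bad = int(np.flatnonzero(~np.isfinite(flt) | (flt != np.round(flt)))[0])
                raise DataError(f"non-integral count at record {bad}: {counts[bad]!r}")
            counts = flt.astype(np.int64)
        if np.any(counts < 0):
            bad = int(np.flatnonzero(counts < 0)[0])
            raise DataError(f"negative count at record {bad}: {counts[bad]}")
        self.counts = counts.astype(np.int64)

        cov = pd.DataFrame(self.covariates)
        if len(cov) != n:
            raise DataError(f"covariates have {len(cov)} rows, expected {n}")
        mat = cov.to_numpy(dtype=float)
        if mat.size and not np.all(np.isfinite(mat)):
            r, c = np.argwhere(~np.isfinite(mat))[0]
            raise DataError(
                f"missing/non-finite covariate value at record {r}, "
                f"column {cov.columns[c]!r} (imputation is not supported)"
            )
        self.covariates = cov

        if self.offsets is None:
            self.offsets = np.zeros(n)
        off = np.asarray(self.offsets, dtype=float)
        if off.shape != (n,):
            raise DataError(f"offsets has shape {off.shape}, expected ({n},)")
        if not np.all(np.isfinite(off)):
            bad = int(np.flatnonzero(~np.isfinite(off))[0])
            raise DataError(f"non-finite offset at record {bad}")
        self.offsets = off

        strata = np.asarray(self.strata, dtype=object)
        if strata.shape != (n,):
            raise DataError(f"strata has shape {strata.shape}, expected ({n},)")
        if any(s is None or (isinstance(s, float) and np.isnan(s)) for s in strata):
            raise DataError("every record must carry a stratum label")
        self.strata = strata

    # -- convenience -------------------------------------------------------

    @classmethod
    def from_arrays(
        cls,
        dates,
        counts,
        covariates,
        offsets=None,
        strata=None,
        scheme: str = "year_month_dow",
    ) -> "StratifiedSeries":
        """Build a series, deriving strata from ``scheme`` when not given."""
        dates = _coerce_dates(dates)
        if strata is None:
            strata = make_strata(dates, scheme)
        return cls(dates=dates, counts=counts, covariates=covariates,
                   offsets=offsets, strata=np.asarray(strata, dtype=object))

    @property
    def n_records(self) -> int:
        return len(self.dates)

    @property
    def covariate_names(self) -> list[str]:
        return [str(c) for c in self.covariates.columns]

    @property
    def covariate_matrix(self) -> np.ndarray:
        return self.covariates.to_numpy(dtype=float)

    def with_covariate(self, name: str, values: np.ndarray) -> "StratifiedSeries":
        """Return a copy with one extra covariate column appended."""
        cov = self.covariates.copy()
        cov[name] = np.asarray(values, dtype=float)
        return dataclasses.replace(self, covariates=cov)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"date": self.dates, "count": self.counts})
        for c in self.covariates.columns:
            out[c] = self.covariates[c].to_numpy()
        if np.any(self.offsets != 0):
            out["offset"] = self.offsets
        out["stratum"] = self.strata
        return out


@dataclass(eq=False)
class StratumIndex:
    """Stratum → member records, event totals n_s, and activity flags.

    ``labels`` preserves first-appearance order; ``members`` preserves
    record order within each stratum. A stratum is active iff n_s > 0.
    """

    labels: list = field(default_factory=list)
    members: dict = field(default_factory=dict)
    totals: dict = field(default_factory=dict)
    active: dict = field(default_factory=dict)

    @property
    def n_strata(self) -> int:
        return len(self.labels)

    @property
    def active_labels(self) -> list:
        return [s for s in self.labels if self.active[s]]

    @property
    def n_active(self) -> int:
        return sum(1 for s in self.labels if self.active[s])

    def total_events(self) -> int:
        return int(sum(self.totals.values()))


def build_index(series: StratifiedSeries) -> StratumIndex:
    """Index a series by stratum: membership, totals n_s = sum Y_i, activity."""
    idx = StratumIndex()
    for i, s in enumerate(series.strata):
        if s not in idx.members:
            idx.labels.append(s)
            idx.members[s] = []
            idx.totals[s] = 0
        idx.members[s].append(i)
        idx.totals[s] += int(series.counts[i])
    for s in idx.labels:
        idx.members[s] = np.asarray(idx.members[s], dtype=np.intp)
        idx.active[s] = idx.totals[s] > 0
    return idx


# -- file readers ----------------------------------------------------------


@dataclass
class ColumnMapping:
    """Names the columns of an input file.

    ``covariates`` lists the covariate columns in model order; ``offset``
    names a column already on the log scale (optional); ``stratum`` names a
    pre-built stratum label column — when absent, strata are derived from
    the dates with ``scheme``.
    """

    date: str = "date"
    count: str = "count"
    covariates: Sequence[str] = ()
    offset: str | None = None
    stratum: str | None = None
    scheme: str = "year_month_dow"

    @classmethod
    def from_dict(cls, d: Mapping) -> "ColumnMapping":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise DataError(f"unknown column-mapping keys: {sorted(unknown)}")
        return cls(**d)


def read_series(path, format: str = "csv", mapping: ColumnMapping | Mapping | None = None) -> StratifiedSeries:
    """Read a stratified series from delimited text or a Stata ``.dta`` file.

    CSV files need a header row and ISO-8601 dates. Counts must be exactly
    integral (a count of 3.5 is rejected, naming the row). Errors name the
    offending row and column.
    """
    if mapping is None:
        mapping = ColumnMapping()
    elif not isinstance(mapping, ColumnMapping):
        mapping = ColumnMapping.from_dict(dict(mapping))

    path = Path(path)
    if not path.exists():
        raise DataError(f"input file not found: {path}")
    if format == "csv":
        df = pd.read_csv(path)
    elif format == "stata_dta":
        df = pd.read_stata(path)
    else:
        raise DataError(f"unknown input format {format!r} (expected 'csv' or 'stata_dta')")

    needed = [mapping.date, mapping.count, *mapping.covariates]
    if mapping.offset:
        needed.append(mapping.offset)
    if mapping.stratum:
        needed.append(mapping.stratum)
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise DataError(f"missing column(s) {missing} in {path.name}; present: {list(df.columns)}")

    dates = _coerce_dates(df[mapping.date])
    offsets = df[mapping.offset].to_numpy(dtype=float) if mapping.offset else None
    strata = df[mapping.stratum].to_numpy(dtype=object) if mapping.stratum else None
    return StratifiedSeries.from_arrays(
        dates=dates,
        counts=df[mapping.count].to_numpy(),
        covariates=df[list(mapping.covariates)],
        offsets=offsets,
        strata=strata,
        scheme=mapping.scheme,
    )
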
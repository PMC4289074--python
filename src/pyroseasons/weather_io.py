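"""Daily weather tables and the standardized feature matrix.

The analysis operates on daily records of fire-weather variables:

==========  ===============================================  =========
column      meaning                                          units
==========  ===============================================  =========
``rh``      relative humidity                                %
``temp``    air temperature                                  °C
``solar``   solar radiation                                  mW m⁻²
``wind``    wind speed                                       as supplied
``soil``    soil moisture at 30-60 cm depth (strictly > 0)   mm
``rain``    daily rainfall (optional)                        cm
==========  ===============================================  =========

Soil moisture is strongly positively skewed on its natural scale and is
ln-transformed before standardization; every variable entering the
clustering is z-scored so it carries equal weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

#: canonical fire-weather variable order
FIRE_WEATHER_VARIABLES = ("rh", "temp", "solar", "wind", "soil")

#: variables ln-transformed by default before standardization
DEFAULT_LOG_VARS = ("soil",)


class WeatherIOError(ValueError):
    """Raised for malformed weather or rainfall tables."""


def folded_doy(dates: pd.DatetimeIndex) -> np.ndarray:
    """Day of year folded onto 1..365: Feb 29 maps to day 59 and later
    leap-year days shift back by one, so day-of-year windows stay
    comparable across years (circular statistics use a 365-day cycle)."""
    doy = dates.dayofyear.to_numpy()
    leap = dates.is_leap_year
    return np.where(leap & (doy >= 60), doy - 1, doy)


@dataclass
class WeatherSeries:
    """Dated daily weather records.

    ``frame`` is indexed by a strictly increasing, duplicate-free
    ``DatetimeIndex`` (daily resolution; gaps allowed) and holds the
    fire-weather columns plus optional ``rain``.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.frame.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise WeatherIOError("WeatherSeries index must be a DatetimeIndex")
        if idx.name != "date":
            self.frame = self.frame.rename_axis("date")
            idx = self.frame.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise WeatherIOError(f"duplicate date: {dup.date()}")
        if not idx.is_monotonic_increasing:
            raise WeatherIOError("dates must be strictly increasing")
        if "soil" in self.frame.columns:
            soil = self.frame["soil"].dropna()
            if (soil <= 0).any():
                bad = soil.index[soil <= 0][0]
                raise WeatherIOError(
                    f"non-positive soil moisture on {bad.date()} "
                    "(ln transform requires soil > 0)"
                )

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.frame.index

    def gap_days(self) -> pd.DatetimeIndex:
        """Calendar days missing from the record span."""
        full = pd.date_range(self.frame.index[0], self.frame.index[-1], freq="D")
        return full.difference(self.frame.index)


@dataclass
class FeatureMatrix:
    """Day × variable matrix after transformation and z-scoring.

    ``values`` holds z-scores (sample SD, n−1 denominator); ``raw_values``
    the post-transform, pre-standardization values kept for ANOVA on the
    original scales.  Rows with any missing variable are dropped and their
    dates recorded in ``dropped_dates``.
    """

    dates: pd.DatetimeIndex
    variables: tuple[str, ...]
    values: np.ndarray
    raw_values: np.ndarray
    transform_log: frozenset[str]
    dropped_dates: pd.DatetimeIndex = field(
        default_factory=lambda: pd.DatetimeIndex([])
    )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.dates, columns=self.variables)

    def write_csv(self, path) -> None:
        self.to_frame().rename_axis("date").to_csv(path)


def read_daily_weather(path, column_map: dict[str, str] | None = None) -> WeatherSeries:
    """Read a daily weather CSV into a :class:`WeatherSeries`.

    Parameters
    ----------
    path : str or file-like
        CSV with a header row; must contain a ``date`` column (ISO-8601)
        and the mapped weather columns.
    column_map : dict, optional
        Mapping ``canonical name -> CSV column name`` for files whose
        headers differ from the canonical ones.
    """
    raw = pd.read_csv(path)
    if column_map:
        rename = {src: dst for dst, src in column_map.items()}
        missing = set(column_map.values()) - set(raw.columns)
        if missing:
            raise WeatherIOError(f"mapped columns absent from CSV: {sorted(missing)}")
        raw = raw.rename(columns=rename)
    if "date" not in raw.columns:
        raise WeatherIOError("CSV must contain a 'date' column")

    try:
        dates = pd.to_datetime(raw["date"], format="ISO8601")
    except (ValueError, TypeError):
        parsed = pd.to_datetime(raw["date"], format="ISO8601", errors="coerce")
        bad = int(np.flatnonzero(parsed.isna())[0])
        raise WeatherIOError(
            f"unparseable date {raw['date'].iloc[bad]!r} at data row {bad + 1}"
        ) from None

    cols = [c for c in (*FIRE_WEATHER_VARIABLES, "rain") if c in raw.columns]
    data = {}
    for c in cols:
        vals = pd.to_numeric(raw[c], errors="coerce")
        bad_rows = np.flatnonzero(vals.isna() & raw[c].notna())
        if bad_rows.size:
            r = int(bad_rows[0])
            raise WeatherIOError(
                f"unparseable value {raw[c].iloc[r]!r} in column {c!r} "
                f"at data row {r + 1}"
            )
        data[c] = vals.to_numpy(float)

    frame = pd.DataFrame(data, index=pd.DatetimeIndex(dates, name="date"))
    series = WeatherSeries(frame.sort_index() if frame.index.is_monotonic_increasing
                           else frame)
    gaps = series.gap_days()
    if len(gaps):
        log.info("weather record has %d gap day(s) between %s and %s",
                 len(gaps), series.dates[0].date(), series.dates[-1].date())
    return series


def write_daily_weather(series: WeatherSeries, path) -> None:
    """Write a :class:`WeatherSeries` back to CSV (round-trip safe)."""
    series.frame.rename_axis("date").to_csv(path)


def skewness_report(
    series: WeatherSeries,
    variables: tuple[str, ...] = FIRE_WEATHER_VARIABLES,
    threshold: float = 1.0,
) -> pd.DataFrame:
    """Adjusted Fisher–Pearson sample skewness per variable.

    A variable is flagged when ``|skew| > threshold`` — the screen that
    identifies soil moisture as needing the ln transform.
    """
    rows = []
    for v in variables:
        x = series.frame[v].dropna().to_numpy(float)
        if x.size < 3:
            raise WeatherIOError(f"skewness of {v!r} needs >= 3 values")
        if np.ptp(x) == 0:
            raise WeatherIOError(f"skewness undefined for constant variable {v!r}")
        g = float(stats.skew(x, bias=False))
        rows.append({"variable": v, "skewness": g, "flagged": abs(g) > threshold})
    return pd.DataFrame(rows).set_index("variable")


def transform_and_standardize(
    series: WeatherSeries,
    variables: tuple[str, ...],
    log_vars: tuple[str, ...] = DEFAULT_LOG_VARS,
) -> FeatureMatrix:
    """Ln-transform ``log_vars`` then z-score every variable.

    Column order follows ``variables`` exactly (downstream
    eigen-decompositions depend on it).  Days missing any selected
    variable are dropped.
    """
    log_vars = tuple(v for v in log_vars if v in variables)
    unknown = set(variables) - set(series.frame.columns)
    if unknown:
        raise WeatherIOError(f"variables absent from series: {sorted(unknown)}")

    sub = series.frame[list(variables)]
    complete = sub.notna().all(axis=1)
    dropped = sub.index[~complete]
    sub = sub.loc[complete]
    if sub.empty:
        raise WeatherIOError("no complete rows after missing-value removal")

    raw = sub.to_numpy(float).copy()
    for v in log_vars:
        j = variables.index(v)
        if (raw[:, j] <= 0).any():
            raise WeatherIOError(f"ln transform of {v!r} requires positive values")
        raw[:, j] = np.log(raw[:, j])

    sd = raw.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise WeatherIOError(f"zero-variance variable: {variables[zero[0]]!r}")
    values = (raw - raw.mean(axis=0)) / sd

    if len(dropped):
        log.info("dropped %d incomplete day(s)", len(dropped))
    return FeatureMatrix(
        dates=sub.index,
        variables=tuple(variables),
        values=values,
        raw_values=raw,
        transform_log=frozenset(log_vars),
        dropped_dates=dropped,
    )
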
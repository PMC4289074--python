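"""Conventional two-season (wet/dry) reference model from cumulative
rainfall anomalies (CRA).

The anomaly is the running sum of daily rainfall minus the long-term
mean daily rainfall, accumulated within "rainfall years" anchored at a
dry-season month (January by default, i.e. calendar years) so the wet
season lies in the interior of each year.  Within a rainfall year the anomaly falls during
the dry season and rises during the wet season, so wet-season onset is
the day after the anomaly's minimum and wet-season end is the day of its
maximum.  The resulting two-level day partition provides the reference
mean R² against which multivariate seasonal models are compared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_selection import per_variable_r2
from .weather_io import FeatureMatrix


@dataclass
class CRASeasons:
    per_year: pd.DataFrame   # rainfall_year, onset/end dates and doys, duration
    labels: pd.Series        # per-day 'wet' / 'dry'
    anomaly: pd.Series       # per-day cumulative rainfall anomaly (cm)


def _rainfall_year(dates: pd.DatetimeIndex, anchor_month: int) -> np.ndarray:
    """Year id of the rainfall year each date belongs to (the id is the
    calendar year in which the rainfall year starts)."""
    y = dates.year.to_numpy()
    return np.where(dates.month.to_numpy() >= anchor_month, y, y - 1)


def cumulative_rainfall_anomaly(
    rain: pd.Series,
    anchor_month: int = 1,
    smooth_days: int | None = None,
) -> pd.Series:
    """Per-day anomaly A(d) = Σ_{i≤d} (rᵢ − r̄) within each rainfall year.

    ``r̄`` is the long-term mean daily rainfall over the whole record.
    ``smooth_days`` optionally centre-smooths the daily rainfall with a
    rolling mean before accumulating.
    """
    if (rain < 0).any():
        raise ValueError("rainfall must be non-negative")
    if (rain.index[-1] - rain.index[0]).days < 2 * 365 - 1:
        raise ValueError("cumulative rainfall anomaly needs >= 2 full years")
    r = rain.astype(float)
    if smooth_days:
        r = r.rolling(smooth_days, center=True, min_periods=1).mean()
    rbar = float(r.mean())
    dev = r - rbar
    year = _rainfall_year(r.index, anchor_month)
    return dev.groupby(year).cumsum().rename("anomaly")


def cra_seasons(rain: pd.Series, anchor_month: int = 1,
                smooth_days: int | None = None) -> CRASeasons:
    """Delineate wet and dry seasons per rainfall year from the CRA.

    Onset = day after the anomaly minimum, end = day of the anomaly
    maximum.  Years whose maximum does not follow the minimum are
    degenerate: they are labelled all-dry, flagged, and excluded from
    the per-year means.  Incomplete edge years are skipped.
    """
    anomaly = cumulative_rainfall_anomaly(rain, anchor_month, smooth_days)
    year = _rainfall_year(anomaly.index, anchor_month)
    labels = pd.Series("dry", index=anomaly.index, name="season")

    rows = []
    for y in np.unique(year):
        m = year == y
        sub = anomaly[m]
        start = sub.index[0]
        expected_start = pd.Timestamp(year=int(y), month=anchor_month, day=1)
        expected_end = expected_start + pd.DateOffset(years=1) - pd.Timedelta("1D")
        if start != expected_start or sub.index[-1] != expected_end:
            continue  # incomplete rainfall year at the record edge
        i_min = int(sub.to_numpy().argmin())  # earliest on ties
        i_max = int(sub.to_numpy().argmax())
        if i_max <= i_min:
            warnings.warn(f"rainfall year {y}: degenerate anomaly extremes; "
                          "year excluded from onset statistics")
            rows.append({"rainfall_year": int(y), "degenerate": True})
            continue
        onset = sub.index[i_min + 1]
        end = sub.index[i_max]
        labels.loc[onset:end] = "wet"
        rows.append({
            "rainfall_year": int(y),
            "onset": onset, "end": end,
            "onset_doy": int(onset.dayofyear), "end_doy": int(end.dayofyear),
            "duration_days": int((end - onset).days) + 1,
            "degenerate": False,
        })
    per_year = pd.DataFrame(rows)
    return CRASeasons(per_year=per_year, labels=labels, anomaly=anomaly)


def reference_fit(fm: FeatureMatrix, cra_labels: pd.Series):
    """Mean R² of the two-level CRA partition over the fire-weather
    variables — the same ANOVA used for cluster models, with the CRA
    wet/dry labels as the factor."""
    common = fm.dates.intersection(cra_labels.index)
    if len(common) < len(fm.dates):
        missing = len(fm.dates) - len(common)
        raise ValueError(f"CRA labels missing for {missing} feature day(s)")
    lab = cra_labels.loc[fm.dates].map({"dry": 1, "wet": 2}).to_numpy()
    return per_variable_r2(fm.raw_values, lab, fm.variables)
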
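"""Calendar characterization of clusters, the seasonality screen,
representative-model ranking, and season role assignment.

A cluster qualifies as a season when it recurs every year as a
sufficiently long run of days.  Clusters are profiled by mean days per
year, 15-day day-of-year histograms, and circular predominance
intervals (the day-of-year range over which the cluster is the
across-years modal label).  Surviving models are ranked on mean R²
(descending), AIC (ascending) and Pillai's trace (descending); the
representative model minimizes the mean rank, ties broken by smaller
radius.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .mode_clustering import ClusterModel
from .model_selection import CandidateSet, FitStats, usable
from .weather_io import WeatherSeries, folded_doy

log = logging.getLogger(__name__)

HIST_BIN_DAYS = 15
N_BINS = int(np.ceil(366 / HIST_BIN_DAYS))  # 25 bins, last one short

SEASON_ROLES = ("wet", "dry", "fire")


@dataclass
class ClusterSeason:
    """Calendar profile of one cluster."""

    mean_days_per_year: float
    histogram: np.ndarray                       # counts per 15-day bin
    predominance_interval: tuple[int, int] | None  # circular (start, end) doy
    consistency: int                            # min over years of longest run
    role: str = "none"


@dataclass
class SeasonProfile:
    clusters: dict[int, ClusterSeason]
    modal_by_doy: np.ndarray  # length 365; 0 where no labeled day exists


def _circular_runs(values: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal circular runs of constant nonzero value over positions
    1..len(values); returns (value, start, end) with 1-based ends."""
    n = len(values)
    if n == 0:
        return []
    if np.all(values == values[0]):
        return [] if values[0] == 0 else [(int(values[0]), 1, n)]
    # rotate so a boundary is at position 0
    brk = next(i for i in range(1, n + 1) if values[i % n] != values[(i - 1) % n])
    runs = []
    start = brk
    for i in range(1, n + 1):
        a = values[(brk + i) % n]
        b = values[(brk + i - 1) % n]
        if a != b:
            v = int(b)
            if v != 0:
                runs.append((v, start % n + 1, (brk + i - 1) % n + 1))
            start = brk + i
    return runs


def season_profile(model: ClusterModel, dates: pd.DatetimeIndex) -> SeasonProfile:
    """Profile every retained cluster of ``model`` over the calendar."""
    if (dates[-1] - dates[0]).days < 2 * 365 - 1:
        raise ValueError("season profiling needs at least 2 full years")
    labels = model.labels
    doy = folded_doy(dates)
    years = dates.year.to_numpy()
    span_years = (dates[-1] - dates[0]).days / 365.25

    # across-years modal cluster per day of year (ties -> lower cluster id)
    n_ids = max(model.modes) if model.modes else 0
    counts = np.zeros((366, n_ids + 1), dtype=np.int64)
    np.add.at(counts, (doy, labels), 1)
    counts = counts[1:, 1:]  # drop doy 0 pad and the unassigned column
    modal = np.zeros(365, dtype=np.int64)
    any_label = counts.sum(axis=1) > 0
    modal[any_label] = counts[any_label].argmax(axis=1) + 1

    runs = _circular_runs(modal)
    clusters: dict[int, ClusterSeason] = {}
    for c in model.modes:
        mask = labels == c
        hist = np.bincount((doy[mask] - 1) // HIST_BIN_DAYS, minlength=N_BINS)
        # longest consecutive-date run per calendar year, min over years
        consistency = None
        day_num = dates.asi8 // 86_400_000_000_000
        for y in np.unique(years):
            in_y = mask & (years == y)
            if not in_y.any():
                consistency = 0
                break
            dn = day_num[in_y]
            brk = np.flatnonzero(np.diff(dn) != 1)
            edges = np.concatenate(([-1], brk, [dn.size - 1]))
            best = int(np.diff(edges).max())
            consistency = best if consistency is None else min(consistency, best)
        # longest circular predominance run (tie -> earliest start)
        my_runs = [(v, a, b) for v, a, b in runs if v == c]
        interval = None
        if my_runs:
            def _length(r):
                _, a, b = r
                return b - a + 1 if a <= b else 365 - a + 1 + b
            best_run = max(my_runs, key=lambda r: (_length(r), -r[1]))
            interval = (best_run[1], best_run[2])
        clusters[c] = ClusterSeason(
            mean_days_per_year=float(mask.sum() / span_years),
            histogram=hist,
            predominance_interval=interval,
            consistency=int(consistency or 0),
        )
    return SeasonProfile(clusters=clusters, modal_by_doy=modal)


def screen_seasonal(
    profile: SeasonProfile, min_days: int = 10
) -> tuple[bool, list[str]]:
    """Pass iff every retained cluster recurs in every year as a run of
    at least ``min_days`` consecutive days and predominates somewhere."""
    reasons = []
    for c, cs in profile.clusters.items():
        if cs.consistency == 0:
            reasons.append(f"cluster {c}: not consistent across years")
        elif cs.consistency < min_days:
            reasons.append(
                f"cluster {c}: longest run only {cs.consistency} day(s) "
                f"in some year (< {min_days})"
            )
        if cs.predominance_interval is None:
            reasons.append(f"cluster {c}: no predominance interval")
    return (not reasons), reasons


def rank_and_select(
    survivors: list[tuple[ClusterModel, FitStats]]
) -> tuple[ClusterModel, FitStats]:
    """Mean-rank selection over {mean R² desc, AIC asc, Pillai desc};
    ties broken by smaller radius."""
    if not survivors:
        raise ValueError("no surviving candidate models to rank")
    mean_r2 = np.array([s.mean_r2 for _, s in survivors])
    aic = np.array([s.aic for _, s in survivors])
    pillai = np.array([s.pillai for _, s in survivors])
    ranks = (rankdata(-mean_r2) + rankdata(aic) + rankdata(-pillai)) / 3.0
    order = sorted(range(len(survivors)),
                   key=lambda i: (ranks[i], survivors[i][0].R))
    return survivors[order[0]]


def assign_roles(
    model: ClusterModel, series: WeatherSeries
) -> dict[int, str]:
    """Label a 3-cluster model's clusters wet/dry/fire from their weather.

    The fire season has both the highest mean solar radiation and the
    lowest mean relative humidity; of the remaining two, the wet season
    has the higher soil moisture.  Any conflict or tie yields all-'none'
    with a warning.  Models with k != 3 get all-'none'.
    """
    roles = {c: "none" for c in model.modes}
    if model.k != 3:
        return roles
    frame = series.frame
    means = {}
    for c in model.modes:
        m = model.labels == c
        means[c] = {
            "solar": frame["solar"].to_numpy()[m].mean(),
            "rh": frame["rh"].to_numpy()[m].mean(),
            "soil": frame["soil"].to_numpy()[m].mean(),
        }
    by_solar = sorted(means, key=lambda c: -means[c]["solar"])
    by_rh = sorted(means, key=lambda c: means[c]["rh"])
    if means[by_solar[0]]["solar"] == means[by_solar[1]]["solar"]:
        warnings.warn("role assignment: tie on solar radiation; roles left 'none'")
        return roles
    if by_solar[0] != by_rh[0]:
        warnings.warn(
            "role assignment: highest-solar cluster is not lowest-humidity; "
            "roles left 'none'"
        )
        return roles
    fire = by_solar[0]
    rest = [c for c in means if c != fire]
    if means[rest[0]]["soil"] == means[rest[1]]["soil"]:
        warnings.warn("role assignment: tie on soil moisture; roles left 'none'")
        return roles
    wet = max(rest, key=lambda c: means[c]["soil"])
    dry = next(c for c in rest if c != wet)
    roles[fire], roles[wet], roles[dry] = "fire", "wet", "dry"
    return roles


@dataclass
class RepresentativeModel:
    """End result of the season-delineation pipeline."""

    model: ClusterModel
    stats: FitStats
    profile: SeasonProfile
    roles: dict[int, str]
    candidates: CandidateSet
    n_screened: int

    def labels_by_date(self, dates: pd.DatetimeIndex) -> pd.Series:
        return pd.Series(self.model.labels, index=dates, name="cluster")

    def roles_by_date(self, dates: pd.DatetimeIndex) -> pd.Series:
        role = np.array([self.roles.get(int(l), "none") for l in self.model.labels])
        return pd.Series(role, index=dates, name="season")


def select_representative(
    fm,
    series: WeatherSeries,
    R_grid=None,
    CK: int = 50,
    min_days: int = 10,
) -> RepresentativeModel:
    """Sweep, cull, screen, rank, and label: the full model-selection
    pipeline from a feature matrix to the representative seasonal model."""
    from .model_selection import DEFAULT_R_GRID, cull_by_days_per_year, sweep_radius

    if R_grid is None:
        R_grid = DEFAULT_R_GRID
    cands = sweep_radius(fm, R_grid=R_grid, CK=CK)
    cands = cull_by_days_per_year(cands, min_days=min_days)
    survivors = []
    for m, s in usable(cands):
        prof = season_profile(m, fm.dates)
        ok, _reasons = screen_seasonal(prof, min_days=min_days)
        if ok:
            survivors.append((m, s))
    model, stats = rank_and_select(survivors)
    profile = season_profile(model, fm.dates)
    sub_series = WeatherSeries(series.frame.loc[fm.dates])
    roles = assign_roles(model, sub_series)
    return RepresentativeModel(
        model=model, stats=stats, profile=profile, roles=roles,
        candidates=cands, n_screened=len(survivors),
    )
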
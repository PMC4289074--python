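"""Radius sweep, fit statistics, and candidate-model culling.

Candidate seasonal models are produced by sweeping the kernel radius R.
Each model is scored by three fit statistics:

* mean R² — one-way ANOVA R² (SS_between / SS_total) per weather
  variable with cluster as the factor, averaged over variables; computed
  on the post-transform, pre-standardization scale (standardization does
  not change R²);
* AIC — per-cluster Gaussian likelihood with full covariance,
  penalty 2·p with p = k·(d + d(d+1)/2);
* Pillai's trace — tr(B(B+W)⁻¹) from the one-way MANOVA between- and
  within-group cross-product matrices of the standardized variables.

Unassigned days (label 0) are excluded from all fit statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mode_clustering import ClusterModel, cluster, pairwise_sq_dists
from .weather_io import FeatureMatrix, WeatherSeries, transform_and_standardize

log = logging.getLogger(__name__)

#: default radius grid: 40 log-spaced radii in standardized units
DEFAULT_R_GRID = tuple(np.geomspace(0.2, 3.0, 40))

MAX_USEFUL_CLUSTERS = 8  # models with more potential seasons are not useful


@dataclass
class FitStats:
    """Fit statistics of one candidate model."""

    R: float
    k: int
    r2_per_variable: dict[str, float]
    mean_r2: float
    aic: float
    pillai: float
    days_per_year: dict[int, float]


@dataclass
class CandidateSet:
    """Candidate models from one sweep over a shared variable subset."""

    models: list[tuple[ClusterModel, FitStats | None]]
    variable_subset: tuple[str, ...]
    culling_log: list[str] = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        """(R, k, mean_r2, aic, pillai) per candidate — the data behind a
        fit-versus-radius scatter."""
        rows = []
        for m, s in self.models:
            rows.append({
                "R": m.R, "k": m.k,
                "mean_r2": s.mean_r2 if s else np.nan,
                "aic": s.aic if s else np.nan,
                "pillai": s.pillai if s else np.nan,
            })
        return pd.DataFrame(rows)


def _grouped(values: np.ndarray, labels: np.ndarray):
    m = labels > 0
    return np.asarray(values, float)[m], np.asarray(labels)[m]


def per_variable_r2(
    raw_values: np.ndarray,
    labels: np.ndarray,
    variables: tuple[str, ...],
) -> tuple[dict[str, float], float]:
    """One-way ANOVA R² per variable with cluster as factor."""
    X, g = _grouped(raw_values, labels)
    ids = np.unique(g)
    if len(ids) < 2:
        raise ValueError("R² needs at least 2 clusters")
    r2 = {}
    for j, v in enumerate(variables):
        x = X[:, j]
        grand = x.mean()
        ss_t = float(((x - grand) ** 2).sum())
        if ss_t == 0:
            raise ValueError(f"zero total sum of squares for {v!r}")
        ss_b = sum(
            (x[g == c].size) * (x[g == c].mean() - grand) ** 2 for c in ids
        )
        r2[v] = float(ss_b / ss_t)
    return r2, float(np.mean(list(r2.values())))


def _cross_products(values: np.ndarray, labels: np.ndarray):
    X, g = _grouped(values, labels)
    ids = np.unique(g)
    grand = X.mean(axis=0)
    B = np.zeros((X.shape[1], X.shape[1]))
    W = np.zeros_like(B)
    for c in ids:
        Xi = X[g == c]
        d = Xi.mean(axis=0) - grand
        B += Xi.shape[0] * np.outer(d, d)
        C = Xi - Xi.mean(axis=0)
        W += C.T @ C
    return B, W, X, g, ids


def pillai_trace(values: np.ndarray, labels: np.ndarray) -> float:
    """Pillai's trace V = tr(B(B+W)⁻¹) of the one-way MANOVA."""
    B, W, X, g, ids = _cross_products(values, labels)
    if len(ids) < 2:
        raise ValueError("Pillai's trace needs at least 2 clusters")
    if X.shape[0] <= X.shape[1] + len(ids):
        raise ValueError("too few observations for MANOVA")
    T = B + W
    try:
        sol = np.linalg.solve(T, B)
    except np.linalg.LinAlgError as e:
        raise ValueError("singular total cross-product matrix") from e
    return float(np.trace(sol))


def aic_score(values: np.ndarray, labels: np.ndarray,
              reg: float = 1e-6) -> float:
    """Gaussian-mixture-style AIC of a hard clustering.

    Log-likelihood sums per-cluster multivariate-normal densities with
    the cluster's own MLE mean and full covariance; clusters with fewer
    than d+1 members fall back to the pooled covariance, and singular
    covariances are ridge-regularized by ``reg``·I (logged).
    """
    X, g = _grouped(values, labels)
    n, d = X.shape
    ids = np.unique(g)
    if len(ids) < 1:
        raise ValueError("AIC needs at least 1 cluster")

    pooled = np.cov(X, rowvar=False, bias=True) + reg * np.eye(d)
    loglik = 0.0
    for c in ids:
        Xi = X[g == c]
        mu = Xi.mean(axis=0)
        if Xi.shape[0] >= d + 1:
            S = np.cov(Xi, rowvar=False, bias=True)
        else:
            S = pooled
            log.info("cluster %s has < d+1 members; pooled covariance used", c)
        sign, logdet = np.linalg.slogdet(S)
        if sign <= 0:
            S = S + reg * np.eye(d)
            sign, logdet = np.linalg.slogdet(S)
            log.info("singular covariance in cluster %s regularized", c)
        diff = Xi - mu
        mahal = np.einsum("ij,ij->i", diff @ np.linalg.inv(S), diff)
        loglik += -0.5 * (Xi.shape[0] * (d * np.log(2 * np.pi) + logdet)
                          + mahal.sum())
    p = len(ids) * (d + d * (d + 1) // 2)
    return float(-2.0 * loglik + 2.0 * p)


def _days_per_year(model: ClusterModel, dates: pd.DatetimeIndex) -> dict[int, float]:
    span_years = (dates[-1] - dates[0]).days / 365.25 if len(dates) > 1 else 1.0
    span_years = max(span_years, 1e-9)
    out = {}
    for c in model.modes:
        out[c] = float((model.labels == c).sum() / span_years)
    return out


def fit_stats(model: ClusterModel, fm: FeatureMatrix) -> FitStats:
    """All fit statistics for one model (requires k >= 2)."""
    r2, mean_r2 = per_variable_r2(fm.raw_values, model.labels, fm.variables)
    return FitStats(
        R=model.R,
        k=model.k,
        r2_per_variable=r2,
        mean_r2=mean_r2,
        aic=aic_score(fm.values, model.labels),
        pillai=pillai_trace(fm.values, model.labels),
        days_per_year=_days_per_year(model, fm.dates),
    )


def sweep_radius(
    fm: FeatureMatrix,
    R_grid=DEFAULT_R_GRID,
    CK: int = 50,
) -> CandidateSet:
    """One clustering run per radius; models outside 2..8 clusters are
    flagged in the culling log (fit statistics need k >= 2)."""
    grid = sorted(float(r) for r in R_grid)
    if not grid or grid[0] <= 0:
        raise ValueError("R_grid must be non-empty and positive")
    d2 = pairwise_sq_dists(fm.values)
    models: list[tuple[ClusterModel, FitStats | None]] = []
    culls: list[str] = []
    for R in grid:
        try:
            m = cluster(fm.values, R, CK=CK, d2=d2)
        except Exception as e:  # pragma: no cover - defensive
            culls.append(f"R={R:g}: failed ({e}); skipped")
            continue
        if m.k < 2:
            culls.append(f"R={R:g}: k={m.k} < 2; flagged")
            models.append((m, None))
            continue
        s = fit_stats(m, fm)
        if m.k > MAX_USEFUL_CLUSTERS:
            culls.append(f"R={R:g}: k={m.k} > {MAX_USEFUL_CLUSTERS}; flagged")
        models.append((m, s))
    return CandidateSet(models=models, variable_subset=fm.variables,
                        culling_log=culls)


def usable(cs: CandidateSet) -> list[tuple[ClusterModel, FitStats]]:
    """Candidates with fit statistics and 2..8 clusters."""
    return [(m, s) for m, s in cs.models
            if s is not None and 2 <= m.k <= MAX_USEFUL_CLUSTERS]


def screen_variable_subsets(
    series: WeatherSeries,
    full_set: tuple[str, ...],
    CK: int = 50,
    R_grid=DEFAULT_R_GRID,
    log_vars: tuple[str, ...] = ("soil",),
    delta: float = 0.05,
) -> pd.DataFrame:
    """Leave-one-out variable screening for "wrench" variables.

    Sweeps the full set and every leave-one-out subset, recording the
    best mean R² per cluster-number class (2..8).  A variable is a
    wrench when, in every class where both sides produced models, the
    best model from subsets containing it falls at least ``delta``
    below the best model from subsets excluding it.  The radius grid is
    scaled by sqrt(d_subset / d_full) per subset so neighbourhoods
    cover comparable volumes across dimensionalities.
    """
    if len(full_set) < 3:
        raise ValueError("need at least 3 variables to screen")
    subsets = [tuple(full_set)]
    subsets += [tuple(v for v in full_set if v != drop) for drop in full_set]

    best_by_k: dict[tuple[str, ...], dict[int, float]] = {}
    for sub in subsets:
        fm = transform_and_standardize(series, sub, log_vars=log_vars)
        scale = np.sqrt(len(sub) / len(full_set))
        grid = [float(r) * scale for r in R_grid]
        per_k: dict[int, float] = {}
        for m, s in usable(sweep_radius(fm, R_grid=grid, CK=CK)):
            per_k[m.k] = max(per_k.get(m.k, -np.inf), s.mean_r2)
        best_by_k[sub] = per_k

    rows = []
    for v in full_set:
        drop_v = tuple(x for x in full_set if x != v)
        without = best_by_k[drop_v]
        with_v: dict[int, float] = {}
        for sub in subsets:
            if v in sub:
                for k, r2 in best_by_k[sub].items():
                    with_v[k] = max(with_v.get(k, -np.inf), r2)
        shared = sorted(set(without) & set(with_v))
        # every subset containing a wrench variable falls short of the
        # subset excluding it, class by class
        wrench = len(shared) >= 2 and all(
            without[k] >= with_v[k] + delta for k in shared
        )
        rows.append({
            "variable": v,
            "best_without": max(without.values(), default=np.nan),
            "best_with": max(with_v.values(), default=np.nan),
            "classes_compared": len(shared),
            "wrench": wrench,
        })
    out = pd.DataFrame(rows).set_index("variable")
    out.attrs["best_by_subset"] = best_by_k
    return out


def cull_by_days_per_year(cs: CandidateSet, min_days: float = 10.0) -> CandidateSet:
    """Drop models having any retained cluster that averages fewer than
    ``min_days`` days per year."""
    kept: list[tuple[ClusterModel, FitStats | None]] = []
    culls = list(cs.culling_log)
    for m, s in cs.models:
        if s is None:
            kept.append((m, s))
            continue
        thin = [c for c, dpy in s.days_per_year.items() if dpy < min_days]
        if thin:
            culls.append(
                f"R={m.R:g}: cluster(s) {thin} average < {min_days:g} days/yr; dropped"
            )
            continue
        kept.append((m, s))
    if not any(s is not None for _, s in kept):
        log.warning("no candidate models survive the days-per-year cull")
    return CandidateSet(models=kept, variable_subset=cs.variable_subset,
                        culling_log=culls)
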
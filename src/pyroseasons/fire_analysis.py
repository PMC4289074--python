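"""Fire-record ingestion, season attribution, and regime summaries.

Fire records are plain DataFrames with columns

    date      ignition date (datetime64)
    area_ha   burned area in hectares (> 0)
    source    one of {"lightning", "military", "prescribed"}

plus, after :func:`attach_season`, the ignition day's cluster id, season
role, weather vector, and fire-weather-plane coordinates.  Summaries
reproduce the per-source seasonal count/area shares (integer
percentages, rounded half away from zero), top-N largest-fire tables,
and the per-cluster "peak mode" overlay against a finer cluster model.

Two small reference tables from the Avon Park Air Force Range 13-year
fire record ship with the package: the printed top-10 largest lightning
and military fires (with the 8-cluster model's cluster ids and ignition
day weather) and the per-source per-season aggregate counts and areas.
"""

from __future__ import annotations

import warnings
from importlib import resources

import numpy as np
import pandas as pd

from .weather_io import WeatherSeries

VALID_SOURCES = ("lightning", "military", "prescribed")


class FireRecordError(ValueError):
    """Raised for malformed fire-record tables."""


# ---------------------------------------------------------------------------
# packaged reference tables

def _data_path(name: str):
    return resources.files("pyroseasons.data").joinpath(name)


def load_top_fires() -> pd.DataFrame:
    """Published top-10 largest lightning and military fires (20 rows)
    with the 8-cluster model's cluster ids and ignition-day weather."""
    with _data_path("apafr_top_fires.csv").open() as fh:
        df = pd.read_csv(fh, parse_dates=["date"])
    return df


def load_season_source_totals() -> pd.DataFrame:
    """Published per-source, per-season fire counts and burned areas."""
    with _data_path("apafr_season_source_totals.csv").open() as fh:
        return pd.read_csv(fh)


def load_lightning_cluster_areas() -> pd.DataFrame:
    """Published burned-area totals of lightning fires by 8-cluster-model
    cluster (the peak-mode cluster vs the rest)."""
    with _data_path("apafr_lightning_cluster_areas.csv").open() as fh:
        return pd.read_csv(fh)


# ---------------------------------------------------------------------------
# ingestion and joining

def read_fire_records(path) -> pd.DataFrame:
    """Read and validate a fire-record CSV (date, area_ha, source)."""
    raw = pd.read_csv(path)
    need = {"date", "area_ha", "source"}
    missing = need - set(raw.columns)
    if missing:
        raise FireRecordError(f"missing column(s): {sorted(missing)}")
    dates = pd.to_datetime(raw["date"], errors="coerce")
    if dates.isna().any():
        r = int(np.flatnonzero(dates.isna())[0])
        raise FireRecordError(f"bad date {raw['date'].iloc[r]!r} at data row {r + 1}")
    area = pd.to_numeric(raw["area_ha"], errors="coerce")
    if area.isna().any() or (area <= 0).any():
        r = int(np.flatnonzero(area.isna() | (area <= 0))[0])
        raise FireRecordError(
            f"bad area {raw['area_ha'].iloc[r]!r} at data row {r + 1} (must be > 0)"
        )
    bad_src = ~raw["source"].isin(VALID_SOURCES)
    if bad_src.any():
        r = int(np.flatnonzero(bad_src)[0])
        raise FireRecordError(
            f"unknown ignition source {raw['source'].iloc[r]!r} at data row {r + 1}"
        )
    out = raw.copy()
    out["date"] = dates
    out["area_ha"] = area.astype(float)
    return out


def attach_season(
    fires: pd.DataFrame,
    labels_by_date: pd.Series,
    roles: dict[int, str],
    series: WeatherSeries | None = None,
    plane_by_date: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join each fire with its ignition day's cluster, season role,
    weather, and fire-weather-plane coordinates."""
    out = fires.copy()
    idx = labels_by_date.index
    outside = ~out["date"].isin(idx)
    if outside.any():
        bad = sorted(d.date().isoformat() for d in out.loc[outside, "date"])
        raise FireRecordError(f"fire date(s) outside the weather record: {bad}")
    out["cluster"] = labels_by_date.loc[out["date"]].to_numpy()
    out["season"] = [roles.get(int(c), "none") for c in out["cluster"]]
    unassigned = out["cluster"] == 0
    if unassigned.any():
        warnings.warn(f"{int(unassigned.sum())} fire(s) fall on unassigned days")
    if series is not None:
        joined = series.frame.loc[out["date"]]
        for col in series.frame.columns:
            out[col] = joined[col].to_numpy()
    if plane_by_date is not None:
        pj = plane_by_date.loc[out["date"]]
        out["f1"] = pj.iloc[:, 0].to_numpy()
        out["f2"] = pj.iloc[:, 1].to_numpy()
    return out


# ---------------------------------------------------------------------------
# summaries

def round_half_away(x) -> np.ndarray:
    """Round to integer, halves away from zero (printed-table style)."""
    x = np.asarray(x, float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def percentage_shares(totals: pd.Series) -> pd.Series:
    """Integer percentage shares of a vector of non-negative totals."""
    total = float(totals.sum())
    if total == 0:
        return totals * 0
    return pd.Series(
        round_half_away(100.0 * totals / total).astype(int), index=totals.index
    )


def season_source_summary(fires: pd.DataFrame) -> pd.DataFrame:
    """Per (source, season): fire count, total area, mean ± SD of the
    ignition-day weather and day of year, and the per-source integer
    percentage shares of counts and area.

    Day of year uses the plain linear mean, matching the printed-table
    convention (note this understates dispersion for seasons wrapping
    the year end).
    """
    df = fires.copy()
    df["doy"] = pd.DatetimeIndex(df["date"]).dayofyear
    weather_cols = [c for c in ("temp", "rh", "solar", "soil") if c in df.columns]

    rows = []
    for source, sdf in df.groupby("source"):
        counts = sdf.groupby("season")["area_ha"].agg(["count", "sum"])
        count_share = percentage_shares(counts["count"])
        area_share = percentage_shares(counts["sum"])
        for season, row in counts.iterrows():
            sub = sdf[sdf["season"] == season]
            rec = {
                "source": source, "season": season,
                "n_fires": int(row["count"]),
                "total_area_ha": float(row["sum"]),
                "count_share_pct": int(count_share[season]),
                "area_share_pct": int(area_share[season]),
                "doy_mean": float(sub["doy"].mean()),
                "doy_sd": float(sub["doy"].std(ddof=1)) if len(sub) > 1 else np.nan,
            }
            for c in weather_cols:
                rec[f"{c}_mean"] = float(sub[c].mean())
                rec[f"{c}_sd"] = (
                    float(sub[c].std(ddof=1)) if len(sub) > 1 else np.nan
                )
            rows.append(rec)
    return pd.DataFrame(rows)


def shares_from_totals(totals: pd.DataFrame) -> pd.DataFrame:
    """Percentage shares straight from an aggregate (source, season,
    n_fires, area_ha) table — the same rounding used by
    :func:`season_source_summary`."""
    out = []
    for source, sdf in totals.groupby("source"):
        cs = percentage_shares(sdf.set_index("season")["n_fires"])
        ar = percentage_shares(sdf.set_index("season")["area_ha"])
        for season in cs.index:
            out.append({
                "source": source, "season": season,
                "count_share_pct": int(cs[season]),
                "area_share_pct": int(ar[season]),
            })
    return pd.DataFrame(out)


def top_n_fires(fires: pd.DataFrame, source: str, n: int = 10) -> pd.DataFrame:
    """The ``n`` largest fires of one ignition source, area descending,
    ties broken by earlier date."""
    sub = fires[fires["source"] == source]
    if len(sub) < n:
        warnings.warn(
            f"only {len(sub)} {source} fire(s) available (requested {n})"
        )
    ranked = sub.sort_values(["area_ha", "date"], ascending=[False, True])
    return ranked.head(n).reset_index(drop=True)


def peak_mode_overlay(
    fires: pd.DataFrame,
    fine_labels_by_date: pd.Series | None = None,
) -> pd.DataFrame:
    """Per fine-model cluster and source: fire count, total area, and the
    share of the source's total area; flags the "peak mode" — the
    cluster holding the largest share of lightning-burned area.

    When ``fine_labels_by_date`` is omitted the fires must already carry
    a ``cluster`` column (e.g. the packaged top-fires table).
    """
    df = fires.copy()
    if fine_labels_by_date is not None:
        outside = ~df["date"].isin(fine_labels_by_date.index)
        if outside.any():
            raise FireRecordError("fire date(s) outside the fine model's range")
        df["cluster"] = fine_labels_by_date.loc[df["date"]].to_numpy()
    elif "cluster" not in df.columns:
        raise FireRecordError("no cluster column and no fine model supplied")

    agg = (
        df.groupby(["source", "cluster"])["area_ha"]
        .agg(n_fires="count", total_area_ha="sum")
        .reset_index()
    )
    agg["area_share_pct"] = 0.0
    for source, sdf in agg.groupby("source"):
        agg.loc[sdf.index, "area_share_pct"] = (
            100.0 * sdf["total_area_ha"] / sdf["total_area_ha"].sum()
        )
    lightning = agg[agg["source"] == "lightning"]
    if lightning.empty:
        warnings.warn("no lightning fires: peak mode undefined")
        agg["peak_mode"] = False
    else:
        peak = lightning.loc[lightning["total_area_ha"].idxmax(), "cluster"]
        agg["peak_mode"] = agg["cluster"] == peak
    return agg


def bubble_plot_export(fires: pd.DataFrame, min_radius: float = 0.05) -> pd.DataFrame:
    """Plotting table for the fire-weather plane: one row per fire with
    a bubble radius proportional to √area (disc area ∝ burned area),
    floored at ``min_radius``."""
    need = {"f1", "f2", "area_ha", "source", "season"}
    missing = need - set(fires.columns)
    if missing:
        raise FireRecordError(f"missing joined column(s): {sorted(missing)}")
    out = fires[["f1", "f2", "area_ha", "source", "season"]].copy()
    out["radius"] = np.maximum(np.sqrt(out["area_ha"].to_numpy()), min_radius)
    return out
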
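"""Synthetic daily weather and fire records with the seasonal structure
the delineation method assumes.

The generator emulates a humid subtropical fire-weather year with three
latent seasons — wet, dry, and an intervening fire season — whose
per-season means and SDs default to the observed south-central Florida
values (air temperature 24.9±2.4 / 18.1±4.1 / 24.2±3.7 °C for
wet/dry/fire, and so on).  Day-to-day persistence is modelled as AR(1)
noise per variable; soil moisture is generated on the ln scale so its
natural-scale distribution is positively skewed; wind speed is by
default aseasonal (same mean in every season), mimicking its
"wrench-in-the-works" behaviour.  Fire events are Poisson per
(ignition source, season) with log-normal burned areas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .weather_io import WeatherSeries, folded_doy

SOURCES = ("lightning", "military", "prescribed")

#: default latent season windows (day of year, circular partition):
#: fire = 98..173, wet = 174..323, dry = 324..97
DEFAULT_WINDOWS = {"fire": (98, 173), "wet": (174, 323), "dry": (324, 97)}

#: default day-to-day anomaly persistence per variable.  Synoptic-scale
#: variables decorrelate in days; modelled 30-60 cm soil moisture is a
#: hydrologic reservoir with weeks of memory.
DEFAULT_AR1_RHO = {
    "rh": 0.65, "temp": 0.75, "solar": 0.5, "wind": 0.5, "soil": 0.97,
}


@dataclass
class SeasonSpec:
    """One latent season: circular day-of-year window plus per-variable
    mean/SD (natural scale; soil is moment-matched to a log-normal) and
    daily rainfall behaviour."""

    name: str
    doy_window: tuple[int, int]
    means: dict[str, float]
    sds: dict[str, float]
    rain_rate: float = 0.0       # mean daily rainfall, cm
    rain_prob: float = 0.3       # wet-day probability (zero inflation)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.sds.values()):
            raise ValueError(f"season {self.name!r}: all SDs must be > 0")
        if self.means.get("soil", 1.0) <= 0:
            raise ValueError(f"season {self.name!r}: soil mean must be > 0")


def default_seasons() -> list[SeasonSpec]:
    """Three-season defaults matching the observed seasonal weather table."""
    means = {
        "wet":  {"temp": 24.9, "rh": 83.0, "solar": 0.19, "soil": 50.0, "wind": 10.0},
        "dry":  {"temp": 18.1, "rh": 78.0, "solar": 0.15, "soil": 21.5, "wind": 10.0},
        "fire": {"temp": 24.2, "rh": 72.0, "solar": 0.28, "soil": 19.2, "wind": 10.0},
    }
    sds = {
        "wet":  {"temp": 2.4, "rh": 5.0, "solar": 0.05, "soil": 34.2, "wind": 3.0},
        "dry":  {"temp": 4.1, "rh": 8.0, "solar": 0.05, "soil": 16.3, "wind": 3.0},
        "fire": {"temp": 3.7, "rh": 6.0, "solar": 0.03, "soil": 11.5, "wind": 3.0},
    }
    rain = {"wet": (0.66, 0.7), "dry": (0.18, 0.25), "fire": (0.20, 0.3)}
    return [
        SeasonSpec(name, DEFAULT_WINDOWS[name], means[name], sds[name],
                   rain_rate=rain[name][0], rain_prob=rain[name][1])
        for name in ("wet", "dry", "fire")
    ]


def default_fire_rates() -> dict[tuple[str, str], float]:
    """Expected fires per year per (source, season), scaled from 13 years
    of observed counts."""
    counts = {
        ("lightning", "wet"): 13, ("lightning", "dry"): 3, ("lightning", "fire"): 43,
        ("military", "wet"): 17, ("military", "dry"): 44, ("military", "fire"): 51,
        ("prescribed", "wet"): 118, ("prescribed", "dry"): 341,
        ("prescribed", "fire"): 205,
    }
    return {k: v / 13.0 for k, v in counts.items()}


def default_fire_sizes() -> dict[tuple[str, str], tuple[float, float]]:
    """Log-normal (mu, sigma) of burned area (ha) per (source, season),
    moment-matched so the mean area equals observed total area / count."""
    total_area = {
        ("lightning", "wet"): 152, ("lightning", "dry"): 521,
        ("lightning", "fire"): 6093,
        ("military", "wet"): 1154, ("military", "dry"): 5853,
        ("military", "fire"): 11115,
        ("prescribed", "wet"): 15269, ("prescribed", "dry"): 69681,
        ("prescribed", "fire"): 41129,
    }
    counts = {k: v * 13.0 for k, v in default_fire_rates().items()}
    sigma = {"lightning": 1.5, "military": 1.5, "prescribed": 1.0}
    out = {}
    for key, area in total_area.items():
        mean = area / counts[key]
        s = sigma[key[0]]
        out[key] = (math.log(mean) - 0.5 * s * s, s)
    return out


@dataclass
class SynthConfig:
    """Study-condition parameters of the generator.

    ``seed`` is mandatory — reproducibility is part of the contract.
    """

    seed: int | None = None
    n_years: int = 17
    start_year: int = 1993
    seasons: list[SeasonSpec] = field(default_factory=default_seasons)
    ar1_rho: float | dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AR1_RHO)
    )
    transition_sd_days: float = 10.0
    fire_rates: dict[tuple[str, str], float] = field(default_factory=default_fire_rates)
    fire_size: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=default_fire_sizes
    )

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("SynthConfig.seed is required")
        if self.n_years < 2:
            raise ValueError("n_years must be >= 2")
        if any(r < 0 for r in self.fire_rates.values()):
            raise ValueError("fire rates must be >= 0")
        rhos = (self.ar1_rho.values() if isinstance(self.ar1_rho, dict)
                else [self.ar1_rho])
        if any(not (0 <= r < 1) for r in rhos):
            raise ValueError("ar1_rho must be in [0, 1)")

    def rho(self, var: str) -> float:
        if isinstance(self.ar1_rho, dict):
            return self.ar1_rho[var]
        return float(self.ar1_rho)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    s2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - 0.5 * s2, math.sqrt(s2)


def _ar1(rng: np.random.Generator, n: int, rho: float) -> np.ndarray:
    """Standard-normal AR(1) path with stationary unit variance."""
    z = np.empty(n)
    eps = rng.standard_normal(n)
    z[0] = eps[0]
    c = math.sqrt(1.0 - rho * rho)
    for t in range(1, n):
        z[t] = rho * z[t - 1] + c * eps[t]
    return z


def _season_boundaries(config: SynthConfig, rng: np.random.Generator,
                       years: np.ndarray) -> dict[int, dict[str, tuple[int, int]]]:
    """Per-year season windows with Gaussian boundary jitter (whole days)."""
    # shared boundaries of the circular partition, in window order
    names = [s.name for s in config.seasons]
    starts = {s.name: s.doy_window[0] for s in config.seasons}
    out: dict[int, dict[str, tuple[int, int]]] = {}
    for y in years:
        jit = {
            n: int(round(starts[n] + rng.normal(0.0, config.transition_sd_days)))
            for n in names
        }
        # wrap into 1..365 and rebuild windows from consecutive starts
        order = sorted(names, key=lambda n: ((jit[n] - 1) % 365) + 1)
        wins = {}
        for i, n in enumerate(order):
            a = ((jit[n] - 1) % 365) + 1
            b = ((jit[order[(i + 1) % len(order)]] - 2) % 365) + 1
            wins[n] = (a, b)
        out[int(y)] = wins
    return out


def _in_window(doy: np.ndarray, window: tuple[int, int]) -> np.ndarray:
    a, b = window
    if a <= b:
        return (doy >= a) & (doy <= b)
    return (doy >= a) | (doy <= b)


def generate_weather(config: SynthConfig) -> tuple[WeatherSeries, pd.Series]:
    """Generate a daily weather series plus its latent season labels.

    Each day's latent season comes from that year's jittered windows;
    each variable is its season mean plus AR(1) anomalies whose
    stationary SD equals the season SD.  Soil is generated on the ln
    scale (moment-matched log-normal), so its natural-scale
    distribution is positively skewed.  Returns ``(series, truth)``
    where ``truth`` is a per-day Series of season names aligned to the
    weather dates.
    """
    rng = np.random.default_rng(config.seed)
    start = pd.Timestamp(year=config.start_year, month=1, day=1)
    end = pd.Timestamp(year=config.start_year + config.n_years - 1, month=12, day=31)
    dates = pd.date_range(start, end, freq="D")
    doy = folded_doy(dates)
    years = dates.year.to_numpy()

    windows = _season_boundaries(config, rng, np.unique(years))
    labels = np.empty(len(dates), dtype=object)
    for y, wins in windows.items():
        in_year = years == y
        for name, win in wins.items():
            labels[in_year & _in_window(doy, win)] = name
    truth = pd.Series(labels, index=dates, name="season")

    by_name = {s.name: s for s in config.seasons}
    frame = pd.DataFrame(index=dates)
    for var in ("temp", "rh", "solar", "wind"):
        z = _ar1(rng, len(dates), config.rho(var))
        mu = np.array([by_name[l].means[var] for l in labels])
        sd = np.array([by_name[l].sds[var] for l in labels])
        frame[var] = mu + sd * z
    # soil on the ln scale -> positively skewed natural scale
    z = _ar1(rng, len(dates), config.rho("soil"))
    ln_mu = np.empty(len(dates))
    ln_sd = np.empty(len(dates))
    for name, spec in by_name.items():
        m = labels == name
        a, b = _lognormal_params(spec.means["soil"], spec.sds["soil"])
        ln_mu[m], ln_sd[m] = a, b
    frame["soil"] = np.exp(ln_mu + ln_sd * z)

    frame["rh"] = frame["rh"].clip(0.0, 100.0)
    frame["solar"] = frame["solar"].clip(lower=1e-3)
    frame["wind"] = frame["wind"].clip(lower=0.0)

    # zero-inflated gamma rainfall per season
    rain = np.zeros(len(dates))
    shape = 0.8
    u = rng.random(len(dates))
    gam = rng.gamma(shape, 1.0, len(dates))
    for name, spec in by_name.items():
        m = labels == name
        if spec.rain_rate > 0:
            wet_day = m & (u < spec.rain_prob)
            scale = spec.rain_rate / (spec.rain_prob * shape)
            rain[wet_day] = gam[wet_day] * scale
    frame["rain"] = rain

    frame = frame[["rh", "temp", "solar", "wind", "soil", "rain"]]
    return WeatherSeries(frame), truth


def generate_fires(config: SynthConfig, truth: pd.Series) -> pd.DataFrame:
    """Draw fire events conditional on the latent season labels.

    Per (source, season): count ~ Poisson(rate × n_years), ignition dates
    uniform over that season's days, burned area log-normal.  Returns a
    DataFrame with columns ``date, area_ha, source`` sorted by date.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0xF19E]))
    rows = []
    for (source, season), rate in config.fire_rates.items():
        days = truth.index[truth.to_numpy() == season]
        if rate <= 0 or len(days) == 0:
            continue
        n = rng.poisson(rate * config.n_years)
        if n == 0:
            continue
        picked = days[rng.integers(0, len(days), n)]
        mu, sigma = config.fire_size[(source, season)]
        areas = rng.lognormal(mu, sigma, n)
        for d, a in zip(picked, areas):
            rows.append({"date": d, "area_ha": float(a), "source": source})
    if not rows:
        return pd.DataFrame(columns=["date", "area_ha", "source"])
    out = pd.DataFrame(rows).sort_values(["date", "area_ha"]).reset_index(drop=True)
    return out
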
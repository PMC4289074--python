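# pyroseasons

Multivariate delineation of **fire-weather seasons** from multi-year
daily weather records, with attribution of fire records (lightning,
military, and prescribed ignitions) to the delineated seasons.

Fire seasonality is usually described with single-variable seasons
(rainfall or temperature).  This package implements a multivariate
alternative for humid savanna–grassland climates such as south-central
Florida: days are clustered directly in the space of the weather
variables that govern fire spread — relative humidity (%), air
temperature (°C), solar radiation (mW m⁻²), wind speed, and 30–60 cm
soil moisture (mm) — revealing a distinct *fire season* of drought,
intense sun, warmth, and low humidity wedged between the conventional
dry and wet seasons.

## Method

1. **Features** — soil moisture is ln-transformed (it is strongly
   right-skewed), and every variable is z-scored so each has equal
   weight (`weather_io`).
2. **Mode clustering** — days are clustered with nonparametric
   uniform-kernel mode seeking: the density at day *x* is
   `f(x) = m(x) / (n·V_R)` with `m(x)` the number of days within
   Euclidean radius *R* of *x*; each day follows its densest neighbour
   uphill and each density mode's basin is a cluster.  Clusters smaller
   than the minimum size `CK = 50` are dissolved into their nearest
   neighbours (`mode_clustering`).
3. **Model selection** — sweeping *R* produces candidate models with
   2–8 clusters, scored by mean one-way-ANOVA *R²* across variables,
   a per-cluster Gaussian AIC, and Pillai's trace
   `V = tr(B(B+W)⁻¹)`; variables that prevent good models ("wrench"
   variables — wind speed in the motivating system) are screened out by
   leave-one-out subset sweeps (`model_selection`).
4. **Seasonality screen and ranking** — a cluster qualifies as a season
   only if it recurs every year as a run of ≥ 10 consecutive days; the
   representative model minimizes the mean rank over the three fit
   statistics (`seasonality`).
5. **Fire-weather plane** — canonical discriminant functions of the
   representative model (eigenvectors of `W⁻¹B`) span a 2-D plane on
   which every day, and every fire, can be placed; classification uses
   quadratic discriminant analysis with exact leave-one-out
   cross-validation (`discriminant`).
6. **Fire attribution** — fire records join their ignition day's
   season; per-source seasonal count/area shares, top-10 tables, and
   "peak fire mode" overlays are produced (`fire_analysis`).
7. **Reference and validation** — a conventional two-season model from
   cumulative rainfall anomalies `A(d) = Σ_{i≤d}(rᵢ − r̄)` provides the
   baseline fit (`cra_baseline`); random-partition re-analysis checks
   stability (`validation`).

A seeded synthetic-data generator (`synthetic_data`) reproduces the
three-season weather structure (per-season means/SDs from the published
seasonal summary, AR(1) day-to-day persistence, log-normal soil
moisture, seasonal rainfall, per-source fire regimes) so the entire
pipeline is testable without access to station data.

## Worked example

```python
import numpy as np
import pyroseasons as ps

cfg = ps.SynthConfig(seed=1)                      # 17 years of daily weather
series, truth = ps.generate_weather(cfg)
fm = ps.transform_and_standardize(series, ("rh", "temp", "solar", "soil"))
rep = ps.select_representative(fm, series,
                               R_grid=np.geomspace(0.45, 1.2, 24), CK=50)
print(rep.model.k, round(rep.stats.mean_r2, 3), rep.roles)
dm = ps.canonical_functions(fm.values, rep.model.labels, fm.variables)
print([round(f.pct_variance, 1) for f in dm.functions],
      round(dm.misclassification, 3))
```

prints

```
3 0.399 {1: 'dry', 2: 'wet', 3: 'fire'}
[60.3, 39.7] 0.075
```

— a three-season model explaining mean *R²* ≈ 0.40 of the fire-weather
variables (the rainfall-based reference reaches only ≈ 0.11 on the same
data), a fire-weather plane whose first canonical function carries
60 % of the between-season variation, and 7.5 % of days misclassified
by the quadratic discriminant.

The same pipeline is scriptable from a shell:

```bash
pyroseasons synth --seed 1 --years 17 --out-weather w.csv --out-fires f.csv
pyroseasons sweep --weather w.csv --out candidates.csv
pyroseasons cra   --weather w.csv --out cra.csv
```

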
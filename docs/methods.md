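# Methods

## The model

Days of a multi-year daily weather record are treated as points in the
space of fire-weather variables — relative humidity (%), air
temperature (°C), solar radiation (mW m⁻²), wind speed, and soil
moisture at 30–60 cm depth (mm).  Seasons are defined as basins of
attraction of modes of the empirical density of days in this space:
a season is a recurring weather regime, not a calendar convention.
Everything downstream — fit statistics, the canonical discriminant
"fire-weather plane", fire attribution — characterizes these weather
regimes.

### Feature construction

Soil moisture is ln-transformed before standardization; its
distribution is strongly right-skewed (a sample-skewness screen with
the adjusted Fisher–Pearson statistic and threshold |g₁| > 1 flags it).
All variables are then z-scored with the sample SD (n−1), so each
carries equal weight in Euclidean distances.  Days missing any selected
variable are dropped; their dates are recorded.  Column order follows
the caller's variable order, which fixes the orientation of all
eigen-decompositions.

### Uniform-kernel mode clustering

Density at day *i* is `f(i) = m(i)/(n·V_R)` where `m(i)` counts days
within Euclidean radius *R* (the day itself included, so densities are
strictly positive) and `V_R` is the volume of the d-ball.  Each day
points at the qualifying neighbour of maximal density, where neighbour
*j* qualifies if `f(j) > f(i)`, or `f(j) = f(i)` with `j` at a lower
row index.  The plateau clause matters: neighbour counts are integers,
so exact ties are common, and without it every member of an isolated
equal-density pair would become its own mode.  Ties among qualifying
neighbours break to the lowest row index; chains terminate because
(density, −index) strictly increases along them.  Clusters smaller
than `CK` (default 50 days) are dissolved smallest-first (ties by lower
mode index) and their members join the cluster of their nearest
remaining labeled day; the rule iterates until all clusters hold ≥ CK
members.  Cluster ids are renumbered 1..k by ascending mode row index.
The procedure is deterministic for a fixed row order; order
independence holds except on exact density ties, where the declared
index rules decide.

### Fit statistics and model selection

Sweeping *R* over a log-spaced grid yields candidate models; those with
fewer than 2 or more than 8 clusters are flagged as not useful.  Each
candidate is scored by:

* **mean R²** — one-way ANOVA `SS_between/SS_total` per variable with
  cluster as the factor, computed on the post-transform,
  pre-standardization scale (standardization leaves R² unchanged),
  averaged over variables;
* **AIC** — Gaussian hard-clustering likelihood with per-cluster full
  covariance (MLE), penalty `2p` with `p = k(d + d(d+1)/2)`; clusters
  with < d+1 members fall back to the pooled covariance and singular
  covariances are ridge-regularized by 1e-6·I;
* **Pillai's trace** — `tr(B(B+W)⁻¹)` of the one-way MANOVA over the
  standardized variables.

Unassigned days are excluded from all statistics.  Models with any
cluster averaging fewer than 10 days per year are culled.

The **wrench screen** sweeps the full variable set and each
leave-one-out subset, recording the best mean R² per cluster-number
class; a variable is flagged when, in every class where both sides have
models (at least two such classes), every subset containing it trails
the subset excluding it by at least δ = 0.05.  Radius grids are scaled
by √(d_subset/d_full) so neighbourhoods cover comparable volumes across
dimensionalities.  The screen is deliberately conservative: on
synthetic data it produces no false positives, and flags an aseasonal
variable when the record is long enough (about a decade) for per-class
profiles to overlap.

### Seasonality screen, ranking, roles

Per cluster, the calendar profile comprises mean days/year, a 15-day
day-of-year histogram (25 bins anchored at day 1; last bin short), the
circular **predominance interval** (maximal run of days-of-year over
which the cluster is the across-years modal label; the longest run is
reported when there are several), and **consistency** — the minimum
over years of the longest within-year run of consecutive days.  Feb 29
folds onto day 59, so the day-of-year circle has 365 positions.  A
model passes the seasonality screen iff every cluster has consistency
≥ 10 days and a non-empty predominance interval.  Survivors are ranked
on mean R² (descending), AIC (ascending), and Pillai (descending); the
representative model minimizes the mean rank, ties broken by smaller
radius.  For 3-cluster models, roles follow the weather: the fire
season has both the highest mean solar radiation and the lowest mean
relative humidity; of the rest, the wet season has the higher soil
moisture.  Conflicts or exact ties leave all roles "none" with a
warning rather than guessing.

### Discriminant analysis

Canonical functions are eigenvectors of the generalized symmetric
problem `B a = λ W a` (between- and within-group cross-products of the
standardized variables), ordered by eigenvalue, scaled to unit pooled
within-class score variance, and centred on the grand mean.  The
variance share of function *i* is `λᵢ/Σλ` (eigenvalue shares; the
alternative canonical-correlation shares are not used).  Structural
correlations are Pearson correlations of each variable with each score;
each axis is flipped so its largest-|loading| variable loads
positively, making output orientation reproducible.  Approximate F and
p-values for the sequential tests of remaining roots use Rao's
Wilks-lambda approximation.  Classification is quadratic discriminant
analysis — class-specific unbiased covariances, equal priors by default
(proportional priors available) — and leave-one-out cross-validation
downdates the held-out day's own class mean and scatter exactly
(rank-one), so LOOCV is exact at O(n·k·d³) rather than n refits.  When
ignition-day dates and season boundaries are supplied, the fraction of
misclassified days within ±7 days of a predominance boundary is also
reported (circular distance).

### Fire-record attribution

Fire records (ignition date, burned area in ha > 0, source ∈
{lightning, military, prescribed}) join their ignition day's cluster,
season role, weather vector, and plane coordinates.  Summaries report
per (source, season) counts, total areas, weather and day-of-year
mean ± SD, and integer percentage shares rounded half away from zero.
Day of year uses the plain linear mean, matching the printed-table
convention; for a season wrapping the year end this understates the
dispersion.  Top-N tables rank by area, ties by earlier date.  The
peak-mode overlay aggregates fires by a finer model's clusters and
flags the cluster with the largest lightning area share.  Bubble-plot
exports scale radius with √area (disc area proportional to burned
area) with a small floor so tiny fires remain visible.

Two published aggregate tables from the Avon Park Air Force Range
13-year fire record ship with the package (the top-10 largest lightning
and military fires with 8-cluster ids and ignition-day weather, and the
per-source per-season count/area totals); they are reference data, not
synthetic.

### CRA reference model

The cumulative rainfall anomaly is `A(d) = Σ_{i≤d}(rᵢ − r̄)` with `r̄`
the record-long mean daily rainfall, accumulated within rainfall years
anchored at a dry-season month.  The anchor defaults to January
(calendar years): an October anchor coincides with the observed
wet-season end and splits the wet season across year boundaries,
producing degenerate extremes.  Wet-season onset is the day after the
within-year anomaly minimum and the end is the day of the maximum
(earliest on ties); years whose maximum precedes the minimum are
flagged degenerate, labelled all-dry, and excluded from onset
statistics.  The reference fit is the same per-variable ANOVA mean R²
with the two-level CRA partition as the factor.

### Stability validation

Days are partitioned uniformly at random (optionally year-blocked)
into k parts (default 4); each part is re-clustered at the same radius
with CK scaled as max(5, CK·part fraction), and agreement with the
full-data model on that part's days is scored by the Adjusted Rand
Index over days labeled in both.  ARI is a numeric stand-in for a
visual similar-planes comparison.

## The synthetic-data generator

The generator emulates a humid subtropical three-season year.  Latent
season windows partition the day-of-year circle (fire 98–173, wet
174–323, dry 324–97); each year's boundaries are jittered by rounded
Gaussian offsets (SD 10 days).  Each variable is its season's mean plus
AR(1) anomalies whose stationary SD equals the season SD; defaults for
the means and SDs are the published three-season weather summary for
south-central Florida (e.g. air temperature 24.9 ± 2.4 / 18.1 ± 4.1 /
24.2 ± 3.7 °C for wet/dry/fire).  Soil moisture is generated on the ln
scale with moment-matched log-normal parameters, so its natural scale
is right-skewed as observed.  Wind speed is aseasonal by default (same
mean in every season), emulating the wrench variable.  Anomaly
persistence is per-variable — rh 0.65, temp 0.75, solar 0.5, wind 0.5,
soil 0.97 — reflecting synoptic decorrelation times of a few days for
atmospheric variables and the weeks-long memory of modelled 30–60 cm
soil moisture; a scalar rho is accepted for experiments.  Rainfall is
zero-inflated gamma per season (wet 0.66 cm/day at 70 % wet-day
probability; dry 0.18 at 25 %; fire 0.20 at 30 %), chosen so annual
totals and the wet/dry contrast resemble the regional climatology and
the CRA baseline can operate.  Fires are Poisson per (source, season)
with rates scaled from the published 13-year counts and log-normal
areas moment-matched to the published per-cell mean areas (σ = 1.5 for
wildfire sources, 1.0 for prescribed burns).  A seed is mandatory;
output is bit-reproducible.

### What the generator does and does not emulate

It reproduces the marginal per-season distributions, day-to-day
persistence, seasonal timing jitter, soil skewness, rainfall
seasonality, and the per-source fire regime structure.  It does **not**
reproduce the smooth intra-season trajectories of real weather (each
season's mean is flat, so the entire within-season SD is realized as
stationary noise), within-season cross-correlations beyond those
induced by the shared seasonal structure, ENSO-type interannual regime
switching, or spatial structure.  Consequences measured on the default
conditions: the Bayes-optimal classifier of the generator's own labels
attains only ≈ 11 % error (ARI ≈ 0.7 versus truth), so unsupervised
recovery of the truth partition is capped well below that; and
ambiguous weather occurs mid-season as often as at season boundaries,
so cross-validation errors do not concentrate at boundaries the way
they do in real annual-cycle data.  Passing tests therefore demonstrate
correctness of the machinery and of the relative orderings (three-season
models roughly triple the rainfall-reference fit; leave-one-out tracks
resubstitution), not that any clustering could recover latent seasons
sharper than the noise permits.

## Numerical choices

* Pairwise squared distances are computed once per feature matrix
  (float64, O(n²) memory — ~300 MB at 17 years of days) and shared
  across a radius sweep.
* Sweeps at study scale use 24 log-spaced radii in [0.45, 1.2]
  standardized units, the range that produces 2–8 cluster models on
  standardized 4-variable data; the library default grid is the wider
  [0.2, 3.0] × 40.
* Ridge regularization 1e-6·I for singular covariances; pooled-
  covariance fallback for classes with too few members (with warning).
* Ties everywhere break to the lowest row index / earliest date /
  smaller radius, making every pipeline stage deterministic.
* Degenerate inputs raise informative errors rather than propagating
  NaNs: zero-variance columns, non-positive soil moisture, duplicate
  dates, empty survivor sets, fires outside the weather record.

## Known limitations

* Mode-clustering semantics follow the declared strict-ascent-with-
  plateau rule, verified against an exhaustive oracle; no claim of
  bit-parity with any particular legacy implementation is made.
* The AIC construction (per-cluster Gaussian) is one reasonable choice
  among several; it is declared, not canonical.
* Whether the canonical variance split refers to eigenvalue shares or
  canonical-correlation shares is convention-dependent; eigenvalue
  shares are used here.
* The linear day-of-year mean in fire summaries misstates the centre of
  seasons that wrap the year end (the dry season); circular statistics
  are deliberately not substituted to keep outputs comparable with the
  printed-table convention.
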
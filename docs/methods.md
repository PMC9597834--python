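# Methods

This note records the models, estimators, and design decisions behind
`gwforage`, in the spirit of the methods appendices that accompany
simulation-backed analysis packages.

## Survey counting model

A transect survey is treated as a census of foraging whales along a
fixed route. Observation units are individuals, groups (members share
one location and the group contributes its size to the count), and
cow–calf pairs, which contribute exactly **one** whale to the count but
are retained as a flagged unit for the spatial and acoustic stages. No
detection-probability correction is applied: the survey design (slow
vessel, 360° coverage, aborts in poor visibility) treats the counts as
complete within the surveyed strip.

Season summaries use: mean whales/survey over **all** transects
including zero-whale passes (the denominator is survey effort, not whale
encounters); the maximum count; the peak date in days elapsed from the
season start (24 May = day 0), ties broken to the earliest date; and the
adjusted Fisher–Pearson sample skewness and excess kurtosis of the
within-season count series. Skewness and kurtosis are undefined (NaN,
never zero-divided) with fewer than 3 transects or fewer than 2 distinct
counts. Both excess and raw kurtosis are emitted; excess is the default.
A year is "high" when its mean is strictly above the transect-weighted
global mean of all years; equality is classed "low", reading "above the
mean" strictly.

## Time-series diagnostics

The within- and between-year count series are characterized with:

- **ACF**, biased (1/n) estimator, white-noise bands ±1.96/√n;
  **PACF** by Durbin–Levinson on the biased ACF (so pacf[1] = acf[1]);
  lags limited to below half the series length.
- **Persistence residuals**: residual[t] = obs[t] − obs[t−1] for every
  consecutive pair (count = n − 1). The chronological first 66% is the
  training window of the naïve forecast; summaries
  (count/mean/sd/min/max) are reported for the full residual series and
  for the held-out third.
- **Dickey–Fuller** in its non-augmented form (lag order 0, intercept,
  no trend) by default — augmentation is configurable but not assumed —
  with 1/5/10% critical values. The pooled all-years series is analyzed
  as contiguous across winters, deliberately letting the late-season
  state face the next spring; a per-year mode covers the within-season
  rows.
- **Runs test** dichotomized about the median (normal approximation,
  two-sided, no continuity correction); degenerate dichotomies are
  errors, not silent zeros.
- **Ljung–Box** portmanteau statistics at lags 1..k, and lagged
  **cross-correlation** between annual series capped at 10 years of lag
  with pairwise deletion of missing years (no interpolation); lags with
  fewer than 3 overlapping pairs are flagged undefined.

These are thin wrappers over statsmodels; the test suite checks them
against independently hand-rolled brute-force implementations on all
short instances and against known processes (AR(1) recovery, random-walk
and white-noise calibration at the nominal 5% level).

## Site fidelity

Residency is the **inclusive** span between first and last sighting in a
season (single sighting → 1 day; an exclusive span could never produce
the observed minimum of one day). A whale is a *return* whale iff its
sightings span ≥ 2 distinct years, assessed retrospectively over the
whole catalogue — so per-year return proportions count whales identified
that year that ever returned, matching how fidelity tables are reported.
Per-year mean residency is given both including and excluding 1-day
(single-sighting) whales, since conventions differ. Duplicate catalogue
rows are merged with a logged warning. Calf linkage relies on supplied
mother IDs and weaning-year flags; no inference from images is
attempted.

## Spatial statistics

"Straight-line" inter-whale distances are great-circle (haversine)
distances on a 6371 km sphere, reported in meters; at bay scale
(≤ 10 km) this differs from planar distance by < 0.1% and avoids an
arbitrary projection choice. Each individual, group, or cow–calf pair is
one unit in the symmetric, zero-diagonal distance matrix; the
nearest-neighbor distance of a unit is its minimum off-diagonal entry,
and the snapshot mean is defined only with ≥ 2 units (a single whale has
no inter-individual distance). Co-located units (distance 0) are legal
and flagged as same-patch.

Heat grids bin whale counts into half-open [lo, hi) cells in both axes,
origin at the bounding-box corner; a point exactly on a cell edge joins
the higher cell (implemented with a 10⁻⁹-cell nudge against float
rounding of exact boundaries). Counts are conserved exactly: cells plus
an explicit overflow bucket (for points outside a user-supplied box) sum
to the monthly whale total. Monthly assignment is by calendar month of
the observation timestamp. Cell size is a configuration parameter
(default 0.01°) with no claim of matching any particular published map.

## Detection-range model

Detection is the passive sonar equation with spherical spreading and no
additional attenuation (appropriate for low-frequency moans over a few
kilometers): a call at range r is heard when
SL − 20·log10(r/1 m) > NL, with SL drawn Normal(156.9, 11.4²) dB re
1 µPa @ 1 m (the published moan source level). "Heard" means strictly
greater than the ambient level, with no detection-threshold offset
(configurable). The Monte Carlo estimator (default 10⁵ draws, explicit
seed) is the primary path; the closed form
Φ((SL̄ − 20·log10 r − NL)/σ_SL) serves as the independent oracle in
tests and backs the per-minute radius series, where the radius at
detection probability p is r* = 10^((SL̄ − NL − σ_SL·Φ⁻¹(p))/20),
floored at the 1 m reference (noisy minutes beyond 4 SD are flagged).
Because no probability criterion for "detection radius" is standard, it
is defined at p = 0.5, and the series is summarized by the radii
exceeded 10% and 90% of minutes — the occasional maximum extent and the
reliable floor.

## Acoustic bookkeeping

Call classes follow the standard gray-whale repertoire (class one
knocks, class two sweeps, class three moans, class four rumbles) plus
motherese, which is tallied but **excluded from all foraging-call rate
statistics** since it occurs only between cows and calves. Because
published tallies mix denominators, class percentages are reported
against both the all-calls and the core (non-motherese) totals, with no
attempt to reconcile either convention. Call rate is calls/hour/whale
present; hours with zero whales keep their counts but have undefined
rates. The aural-visual schedule samples every fifth full day from the
first full deployment day (≈ 20% day coverage) plus transect-concurrent
hours. Year-to-year rate comparisons use a standard Mann–Whitney U
wrapper.

## Driver importance

Annual whale metrics and environmental indices enter a year × (variable
× lag) table with exact shift semantics (lag-k at year t = source at
t − k; the first k years are missing). Variables are screened pairwise
by |Spearman rs| against a collinearity cap (default 0.95, later column
dropped). Importance is the **explained-deviance share of univariate
penalized-spline fits**: each predictor is fit alone (intercept +
B-spline basis, default df 5 for ≤ 20 annual rows), smoothing chosen on
a fixed log-spaced penalty grid by GCV = n·RSS/(n − edf)², shares
clipped at 0 and normalized to sum to 1. Univariate fits are the point:
each score reflects a variable's influence without the others.
The procedure is deterministic given the table and configuration. This
importance statistic is a declared convention — other GAM-based
importance definitions exist — so rankings, not raw scores, are the
meaningful output, and only structural properties (planted-driver
recovery, null flatness) are asserted.

## Synthetic generator

The generator's defaults are the study conditions the analyses assume:
20 seasons of 9–21 transects between 24 May and 6 September, with three
discarded burn-in seasons so year 1 starts in regime.

**Prey–whale dynamics.** A latent prey biomass (arbitrary units,
capacity 100) sets the season's attendance intensity
λ_y = a·(P_start − T)₊ with attraction threshold T = 30 and
a = 0.35 whales/transect per unit excess — whales are drawn and held
only above a prey threshold. Counts are Poisson around λ_y modulated by
a unit-mean Gaussian-hump seasonal profile (random mid-summer peak), so
seasons show mid-July–mid-August peaks and right skew. Prey falls by
0.035 units per realized whale-day and recovers logistically (rate
1.2/yr) between seasons. The removal response exceeds unity
(a · removal · season length ≈ 1.3), so a heavy year overshoots:
high and low years alternate (negative lag-1 autocorrelation of annual
means in essentially every replicate) and recovery from a heavy year
takes 3–4 seasons. Zero attraction intensity is an exact zero-count
limit; capacity is a fixed point when removal is zero.

**Catalogue.** A loyal pool (40 whales, per-year presence probability
0.7) draws residency windows around 28 days; single-visit whales arrive
Poisson(0.18 × excess prey) with 18-day windows — the 10-day gap is the
injected fidelity signal. Both pools share an additive prey-coupled
residency term (±4 days over the prey range), which induces the positive
residency-vs-whale-number correlation without disturbing the gap.
Whales are sighted on every transect date inside their window; because
windows are observed only at transect dates, estimated spans lose about
one inter-transect interval at each end for both pools, so the
*difference* is recovered nearly unbiased (within ±2 days over
replicates) even though absolute residencies are attenuated. Calves of
loyal whales enter the catalogue with mother links and return in later
years with probability increasing in weaning-year residency.

**Locations and calls.** Units scatter (σ ≈ 700 m) around a bay center
that drifts north 0.02°/month through the season; cow–calf units are
displaced an extra ~1.2 km from the corpus. Call streams are per-class
Poisson at 0.65 calls/hour/whale weighted by a logistic knock/moan
mixture switching around a 400 m mean nearest-neighbor distance
(knocks short-range, moans long-range, sweeps neutral, rumbles rare);
motherese is emitted only when pairs are present. Ambient noise is
i.i.d. Normal(100, 8²) dB per minute over the analyzed windows.

**What the generator does not emulate:** observation error in counts,
weather-driven survey gaps, prey-patch spatial structure (depletion is
site-wide, not patchwise), individual heterogeneity in call rates,
tides/weather structure in ambient noise, and coastline geometry.
Passing tests therefore demonstrate that the estimators recover known
structure of this class — lagged predator–prey signal, pool residency
gaps, distance-dependent call mixtures — not that any particular field
dataset satisfies these assumptions.

**Randomness.** One RNG substream per sub-generator (dynamics,
catalogue, locations, calls, noise), spawned from the master seed:
identical configurations are bit-identical, and modules can be
regenerated independently.

## Numerical and edge-case conventions

- Peak-date ties → earliest date; order of transects never matters.
- Constant series → ACF/PACF and rank correlations are flagged
  undefined, never returned as 0.
- Cross-correlation overlap < 3 after lagging → NaN, flagged.
- Detection radius floors at the 1 m reference distance; ranges below
  1 m are rejected.
- Importance shares: negative explained-deviance estimates are clipped
  to 0 before normalization; an all-zero vector falls back to uniform.
- Dates are stored ISO-8601; season days are integers from 24 May.

## Problem sizes

Replicate experiments use 100 replicates for recovery checks
(planted-driver ranking, residency gap, call-class signs) and 500 for
test-size calibration, at the study scale of 20 seasons × 9–21
transects; the detection Monte Carlo uses 10⁵ draws per grid point.
These sizes give Monte Carlo standard errors comfortably inside the
asserted tolerances.

## Known limitations

- The Dickey–Fuller wrapper reports the non-augmented statistic by
  default; strongly autocorrelated residual structure would call for a
  positive lag order.
- GAM importance with ≤ 20 annual rows is rank-stable but the absolute
  deviance shares are noisy; they should not be compared across
  datasets.
- The visual–acoustic join assigns calls to at most the snapshot
  windows provided; overlapping windows would double-count and are not
  deduplicated.
- The generator's prey state is scalar per site; analyses of
  patch-level depletion dynamics are out of scope.
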
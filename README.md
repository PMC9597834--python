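# gwforage

Quantitative analysis of gray whale (*Eschrichtius robustus*) foraging
habitat use from long-running coastal survey programs. The package is
aimed at movement ecologists and passive-acoustic-monitoring groups who
hold three kinds of field data for a discrete foraging site:

- **line-transect counts** of foraging whales, repeated every few days
  through a May–September season across many years,
- **photo-identification catalogues** (whale ID × sighting date) for
  residency and site-fidelity bookkeeping, and
- **call logs with per-minute ambient noise** from a moored recorder,
  matched to concurrent visual surveys.

It turns those inputs into the standard battery of analyses used to ask
whether site use is driven top-down (the whales' own prey removal),
bottom-up (ocean conditions acting on prey), or socially (who is calling
to whom, and from how far).

## What it computes

**Foraging intensity** (`transects`): per-season mean/max whales per
survey, peak date (days from 24 May), skewness and kurtosis of the count
series, and the high/low classification of each year against the
all-years global mean. Cow–calf pairs count as one whale; groups count
their size.

**Time-series structure** (`diagnostics`): ACF/PACF with 95% bands,
persistence (naïve) forecast residual summaries, Dickey–Fuller
stationarity, the runs test, Ljung–Box statistics, and lagged
cross-correlation between annual series (lags ≤ 10 years).

**Site fidelity** (`fidelity`): inclusive residency spans
(last − first + 1 days), return vs single-visit classification over the
whole catalogue, per-year return proportions, and Spearman correlations
between fidelity and intensity metrics.

**Spatial use** (`spatial`): whale-count-weighted mean locations by
month (the south-to-north seasonal drift), half-open heat grids exported
as GeoJSON, and per-transect nearest-neighbor distance matrices
(haversine, meters) defining the social context of each survey.

**Acoustics in social context** (`acoustics`): aural-visual sampling
schedules (every fifth full day plus transect-concurrent hours),
call-class distributions against both the all-calls and core-call
denominators, calls/hour/whale rates, visual–acoustic joins with rank
correlations, and a sonar-equation detection-range model:

    RL = SL − TL(r),   TL(r) = 20·log10(r / 1 m),   detect ⟺ RL > NL

with source level SL ~ Normal(156.9, 11.4²) dB re 1 µPa @ 1 m. The
Monte Carlo detection probability has closed form
Φ((SL̄ − 20·log10 r − NL)/σ_SL), and the radius where detection
probability is one half is r* = 10^((SL̄ − NL)/20).

**Environmental drivers** (`drivers`): a year × (variable × lag) feature
table (PDO anomaly, SST, wind, upwelling and spring-transition indices,
plus the whale-derived metrics), Spearman screening, and relative
variable importance from univariate penalized-spline (GAM) fits scored
by explained-deviance share.

**Synthetic data** (`synthetic`): a generator reproducing the structure
the analyses assume — prey depletion by whale-days with logistic
recovery (high/low year alternation, multi-year recovery), loyal vs
single-visit whale pools with a 10-day residency gap, northward
within-season drift, and call mixtures that switch from knocks to moans
as whales spread out. Every analysis is testable against this
generator's recorded truth.

## Worked example

```python
import pandas as pd
import gwforage as g
from gwforage.synthetic import SimulationConfig, generate_dataset

ds = generate_dataset(SimulationConfig(seed=7))
summaries = g.summarize_seasons(ds.transects)
df = pd.DataFrame([s.as_dict() for s in summaries])
print(df[["year", "n_transects", "mean_whales", "max_whales",
          "peak_date_days", "classification"]].head(6).to_string(index=False))
```

```
 year  n_transects  mean_whales  max_whales  peak_date_days classification
 1997           18     8.222222          22              69           high
 1998           18     3.388889           6              32            low
 1999           20     8.050000          14              57           high
 2000           21     5.571429          14              52            low
 2001           19     4.105263          11              65            low
 2002            9     7.000000          14              54           high
```

A heavy 1997 season (8.2 whales/survey, peak count 22) is followed by a
depleted 1998 (3.4 whales/survey) — the prey-recovery alternation the
time-series diagnostics are designed to detect. Continuing:

```python
fid = g.classify_catalogue(ds.catalogue)
print("catalogued %d whales, %.1f%% single-visit"
      % (fid.total_individuals, fid.single_visit_proportion))

model = g.DetectionModel()
print("detection radius at NL=96.9 dB: %.0f m" % g.detection_radius(96.9, model))
print("P(detect moan at 2 km, NL=100 dB) = %.3f"
      % g.detection_probability(2000.0, 100.0, model))
```

```
catalogued 160 whales, 45.6% single-visit
detection radius at NL=96.9 dB: 1000 m
P(detect moan at 2 km, NL=100 dB) = 0.211
```

The same computations run from the shell:

```
gwforage all --seed 7 --outdir runs/demo
```

which writes `annual_summary.csv`, `residual_summary.csv`,
`fidelity_summary.csv`, `weighted_means.csv`, `heatgrid.geojson`,
`call_summary.csv`, `detection_radii.csv`, `joined_context.csv`,
`importance.json` and a reproducibility manifest (inputs hashed, seed
recorded; identical seeds give byte-identical outputs).

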
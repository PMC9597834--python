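"""Synthetic multi-season survey, catalogue, location, noise and call data.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage is testable without field data:

* **Prey-whale dynamics** — a latent prey biomass (arbitrary units) is
  depleted within a season in proportion to whale-days of foraging and
  recovers logistically toward capacity between seasons.  Whale counts
  per transect are Poisson with intensity proportional to prey biomass
  above an attraction threshold (foraging whales are drawn and held only
  where prey density exceeds a threshold).  With strong removal this
  produces the high/low alternation of good and depleted years and
  multi-year (3-4 season) recovery after a heavy year.
* **Catalogue** — a loyal pool of individuals returns across years with
  a fixed per-year probability and longer residency; single-visit whales
  arrive in numbers proportional to excess prey and stay for shorter
  spells.  Residency windows shift with prey (an additive prey-coupled
  term common to both pools) so residency correlates with whale numbers
  while the loyal-vs-single residency gap stays at its configured value.
* **Locations** — units scatter around a bay center with a northward
  (monthly) drift through the summer; cow-calf pairs sit farther from
  the main foraging corpus.
* **Calls** — per-whale Poisson call streams whose class mixture depends
  on the mean inter-individual distance: knocks dominate below the knock
  distance threshold, moans above it; motherese occurs only when
  cow-calf pairs are present.

One RNG substream per sub-generator (dynamics, catalogue, locations,
calls, noise), all spawned from the master seed, so identical configs
give bit-identical datasets and modules can be regenerated independently.
"""

from __future__ import annotations

import datetime as dt
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .acoustics import CallRecord
from .fidelity import SightingHistory, catalogue_to_frame
from .spatial import SocialSnapshot, social_context
from .transects import (
    SEASON_END,
    SEASON_START,
    TransectRecord,
    WhaleObservation,
    transects_to_frame,
)

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_prey_whale_dynamics",
    "simulate_sighting_histories",
    "simulate_locations",
    "simulate_call_log",
    "simulate_noise",
    "generate_dataset",
    "write_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Defaults mirror the study's scale: 20 seasons (1997-2016) of 9-21
    transects between 24 May and 6 September, a catalogue split between
    a loyal multi-year pool and single-visit whales with a 10-day
    residency gap, northward within-season drift, and call streams whose
    knock/moan mixture switches around a few-hundred-meter
    inter-individual distance.
    """

    seed: int = 0
    n_years: int = 20
    start_year: int = 1997
    season_start: tuple[int, int] = SEASON_START
    season_end: tuple[int, int] = SEASON_END
    transects_min: int = 9
    transects_max: int = 21
    burn_in_years: int = 3  # discarded spin-up seasons so year 1 starts in regime

    # latent prey dynamics (biomass in arbitrary units)
    prey_capacity: float = 100.0
    prey_recovery_rate: float = 1.2  # logistic rate per year; ~3-4 seasons to recover from a heavy year
    removal_per_whale_day: float = 0.035  # a.u. removed per whale-day of foraging
    whale_attraction_threshold: float = 30.0  # a.u.; no foraging below this
    attraction_intensity: float = 0.35  # whales/transect per a.u. of excess prey at season start

    # catalogue structure
    loyal_pool_size: int = 40
    loyal_return_prob: float = 0.7  # per-year presence probability of a loyal whale
    single_visit_rate: float = 0.18  # whales/season per a.u. of excess prey
    calf_fraction: float = 0.08  # probability a loyal whale-year brings a calf
    loyal_residency_mean: float = 28.0  # days
    single_residency_mean: float = 18.0  # days; gap to loyal is the injected fidelity signal
    residency_prey_coupling: float = 8.0  # additive days per unit excess-prey fraction (zero-centered)
    sighting_prob: float = 1.0  # chance a present whale is photographed on a transect day

    # locations
    base_lat: float = 49.2563
    base_lon: float = -126.1593
    lat_drift_per_month: float = 0.02  # degrees north per month into the season
    location_scatter_m: float = 700.0
    cowcalf_extra_offset_m: float = 1200.0

    # calls (rates in calls/hour/whale)
    call_rate_base: float = 0.65
    knock_distance_threshold: float = 400.0  # m; knock/moan mixture switch point
    distance_mixture_scale: float = 150.0  # m; softness of the switch
    motherese_rate: float = 1.5  # calls/hour per cow-calf pair present
    acoustic_years: int = 2  # final N seasons carry recorder deployments

    # ambient noise
    noise_mean: float = 100.0  # dB re 1 uPa
    noise_sd: float = 8.0

    def __post_init__(self) -> None:
        for name in ("loyal_return_prob", "calf_fraction", "sighting_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {v}")
        for name in (
            "prey_capacity", "prey_recovery_rate", "removal_per_whale_day",
            "whale_attraction_threshold", "attraction_intensity",
            "single_visit_rate", "call_rate_base", "motherese_rate",
            "loyal_residency_mean", "single_residency_mean",
        ):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be a finite nonnegative number, got {v}")
        if not math.isfinite(self.noise_mean) or not math.isfinite(self.noise_sd):
            raise ValueError("noise parameters must be finite")
        if self.n_years < 1 or self.transects_min < 1:
            raise ValueError("need at least one year and one transect")
        if self.transects_min > self.transects_max:
            raise ValueError("transects_min must not exceed transects_max")
        start = dt.date(2000, *self.season_start)
        end = dt.date(2000, *self.season_end)
        if start >= end:
            raise ValueError("season_start must precede season_end")

    @property
    def season_length_days(self) -> int:
        return (dt.date(2000, *self.season_end) - dt.date(2000, *self.season_start)).days

    def rngs(self) -> dict[str, np.random.Generator]:
        """One independent substream per sub-generator, spawned from the seed."""
        names = ("dynamics", "catalogue", "locations", "calls", "noise")
        seqs = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(s) for n, s in zip(names, seqs)}


@dataclass
class SyntheticDataset:
    """Generated dataset plus the generating truth for recovery tests."""

    config: SimulationConfig
    transects: list[TransectRecord]
    catalogue: list[SightingHistory]
    snapshots: list[SocialSnapshot]
    calls: list[CallRecord]
    noise: pd.Series
    truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# stage 1: latent prey and transect counts

def _season_dates(
    config: SimulationConfig, year: int, n_transects: int, rng: np.random.Generator
) -> list[dt.date]:
    """Transect dates: roughly even spacing through the season with jitter."""
    start = dt.date(year, *config.season_start)
    span = config.season_length_days
    base = np.linspace(0, span, n_transects)
    jitter = rng.uniform(-0.4, 0.4, size=n_transects) * (span / max(n_transects, 1))
    days = np.clip(np.round(base + jitter), 0, span).astype(int)
    days = np.unique(days)
    while len(days) < n_transects:  # collisions after rounding: fill gaps
        candidates = np.setdiff1d(np.arange(span + 1), days)
        extra = rng.choice(candidates, size=min(n_transects - len(days), len(candidates)),
                           replace=False)
        days = np.unique(np.concatenate([days, extra]))
    return [start + dt.timedelta(days=int(d)) for d in sorted(days)]


def simulate_prey_whale_dynamics(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[dict, list[TransectRecord]]:
    """Latent prey trajectory and per-transect whale counts.

    The season's whale attendance intensity is set by the prey stock the
    season opens with: lambda_y = attraction_intensity x
    (prey - threshold) where positive, zero otherwise (whales are drawn
    and held only above the threshold).  Within the season counts follow
    a hump-shaped temporal profile (mid-summer peak, normalized to unit
    mean) so seasons show a mid-July-to-mid-August peak with right skew.
    Prey is depleted by ``removal_per_whale_day`` per realized whale-day
    and recovers logistically toward capacity between seasons.  With the
    default calibration the removal response is steep enough
    (attraction_intensity x removal_per_whale_day x season length > 1)
    that a heavy year overshoots: high and low whale years alternate and
    full recovery from a heavy year takes 3-4 seasons.
    """
    if rng is None:
        rng = config.rngs()["dynamics"]
    prey = config.prey_capacity
    prey_start_of_year: list[float] = []
    prey_end_of_year: list[float] = []
    lambda_by_year: list[float] = []
    transects: list[TransectRecord] = []
    span = config.season_length_days
    for iy in range(-config.burn_in_years, config.n_years):
        burn_in = iy < 0
        year = config.start_year + iy
        if not burn_in:
            prey_start_of_year.append(prey)
        excess = max(prey - config.whale_attraction_threshold, 0.0)
        lam_year = config.attraction_intensity * excess
        if not burn_in:
            lambda_by_year.append(lam_year)
        # seasonal shape: Gaussian hump, peak mid-summer, unit mean
        peak_day = rng.uniform(0.45, 0.72) * span
        width = rng.uniform(0.22, 0.38) * span
        grid = np.arange(span + 1)
        shape = np.exp(-0.5 * ((grid - peak_day) / width) ** 2)
        shape /= shape.mean()
        n_tr = int(rng.integers(config.transects_min, config.transects_max + 1))
        dates = _season_dates(config, year, n_tr, rng)
        prev_day = 0
        count = 0
        for it, date in enumerate(dates):
            day = (date - dt.date(year, *config.season_start)).days
            gap = max(day - prev_day, 1)
            prey = max(prey - config.removal_per_whale_day * count * gap, 0.0)
            lam = lam_year * shape[day]
            count = int(rng.poisson(lam))
            # placeholder singleton units carry the count; the location
            # stage re-partitions them into individuals/groups/pairs
            placeholder = tuple(
                WhaleObservation(
                    timestamp=dt.datetime.combine(date, dt.time(hour=10)),
                    lat=math.nan,
                    lon=math.nan,
                )
                for _ in range(count)
            )
            if not burn_in:
                transects.append(
                    TransectRecord(
                        transect_id=f"{year}-T{it + 1:02d}",
                        date=date,
                        completed=True,
                        units=placeholder,
                    )
                )
            prev_day = day
        if not burn_in:
            prey_end_of_year.append(prey)
        # winter recovery: one logistic step toward capacity
        prey = prey + config.prey_recovery_rate * prey * (1.0 - prey / config.prey_capacity)
        prey = min(max(prey, 0.0), config.prey_capacity)
    truth = {
        "prey_start_of_year": prey_start_of_year,
        "prey_end_of_year": prey_end_of_year,
        "lambda_by_year": lambda_by_year,
    }
    return truth, transects


def _partition_units(
    count: int, rng: np.random.Generator, calf_fraction: float
) -> list[tuple[str, int]]:
    """Split a whale count into (unit_type, group_size) tuples.

    Cow-calf pairs count as one whale; groups of 2-4 whales form with
    moderate probability, the rest are singletons.
    """
    units: list[tuple[str, int]] = []
    remaining = count
    while remaining > 0:
        u = rng.random()
        if u < calf_fraction:
            units.append(("cow_calf", 2))
            remaining -= 1
        elif u < calf_fraction + 0.25 and remaining >= 2:
            size = int(rng.integers(2, min(4, remaining) + 1))
            units.append(("group", size))
            remaining -= size
        else:
            units.append(("individual", 1))
            remaining -= 1
    return units


def simulate_locations(
    config: SimulationConfig,
    transects: list[TransectRecord],
    rng: np.random.Generator | None = None,
) -> list[TransectRecord]:
    """Materialize observation units with coordinates on each transect.

    Latitudes drift north as the season progresses
    (``lat_drift_per_month`` degrees per 30 days); cow-calf units are
    displaced an extra ``cowcalf_extra_offset_m`` from the corpus.
    """
    if rng is None:
        rng = config.rngs()["locations"]
    deg_per_m_lat = 1.0 / 111_320.0
    out: list[TransectRecord] = []
    for t in transects:
        count = t.whale_count
        day = (t.date - dt.date(t.year, *config.season_start)).days
        months = day / 30.0
        center_lat = config.base_lat + config.lat_drift_per_month * months
        units = []
        for unit_type, group_size in _partition_units(count, rng, config.calf_fraction):
            scatter = rng.normal(0.0, config.location_scatter_m, size=2)
            offset = scatter.copy()
            if unit_type == "cow_calf":
                theta = rng.uniform(0, 2 * np.pi)
                offset += config.cowcalf_extra_offset_m * np.array(
                    [np.cos(theta), np.sin(theta)]
                )
            lat = center_lat + offset[0] * deg_per_m_lat
            lon = config.base_lon + offset[1] * deg_per_m_lat / np.cos(
                np.radians(config.base_lat)
            )
            units.append(
                WhaleObservation(
                    timestamp=dt.datetime.combine(t.date, dt.time(hour=10)),
                    lat=float(lat),
                    lon=float(lon),
                    unit_type=unit_type,
                    group_size=group_size,
                )
            )
        out.append(
            TransectRecord(
                transect_id=t.transect_id, date=t.date,
                completed=t.completed, units=tuple(units),
            )
        )
    return out


# ---------------------------------------------------------------------------
# stage 2: sighting histories

def simulate_sighting_histories(
    config: SimulationConfig,
    transects: list[TransectRecord],
    truth: dict,
    rng: np.random.Generator | None = None,
) -> tuple[list[SightingHistory], dict]:
    """Per-whale capture histories consistent with the transect seasons.

    Loyal whales are present each year with probability
    ``loyal_return_prob`` and draw residency windows around
    ``loyal_residency_mean``; single-visit whales arrive
    Poisson(``single_visit_rate`` x excess prey) with shorter windows.
    A whale is sighted on every transect date inside its window (thinned
    by ``sighting_prob``).  Residency windows for both pools shift by
    the same prey-coupled additive term, preserving the loyal-vs-single
    gap.  Calves of loyal whales enter the catalogue and return in later
    years with probability increasing in their weaning-year residency.
    """
    if not transects:
        raise ValueError("no transects: generate dynamics first")
    if rng is None:
        rng = config.rngs()["catalogue"]
    by_year: dict[int, list[TransectRecord]] = {}
    for t in transects:
        by_year.setdefault(t.year, []).append(t)
    years = sorted(by_year)
    prey_start = dict(zip(years, truth.get("prey_start_of_year", [config.prey_capacity] * len(years))))

    span = config.season_length_days
    sightings: dict[str, list[dt.date]] = {}
    meta: dict[str, dict] = {}
    residency_truth: list[dict] = []
    calf_roster: dict[str, float] = {}  # calf_id -> return prob in later years
    n_single_total = 0

    def add_whale_year(wid: str, year: int, mean_res: float, pool: str) -> float:
        length = float(np.clip(rng.normal(mean_res, 5.0), 1.0, span))
        start = rng.uniform(0.0, max(span - length, 0.0))
        window0 = dt.date(year, *config.season_start) + dt.timedelta(days=round(start))
        window1 = window0 + dt.timedelta(days=round(length) - 1)
        dates = [
            t.date for t in by_year[year]
            if window0 <= t.date <= window1 and rng.random() < config.sighting_prob
        ]
        if dates:
            sightings.setdefault(wid, []).extend(dates)
            residency_truth.append(
                {"whale_id": wid, "year": year, "pool": pool, "true_residency": length}
            )
        return length

    for year in years:
        excess = max(prey_start[year] - config.whale_attraction_threshold, 0.0)
        excess_frac = excess / max(
            config.prey_capacity - config.whale_attraction_threshold, 1e-9
        )
        res_shift = config.residency_prey_coupling * (excess_frac - 0.5)
        loyal_mean = max(config.loyal_residency_mean + res_shift, 1.0)
        single_mean = max(config.single_residency_mean + res_shift, 1.0)

        for i in range(config.loyal_pool_size):
            wid = f"L{i:03d}"
            if rng.random() < config.loyal_return_prob:
                length = add_whale_year(wid, year, loyal_mean, "loyal")
                meta.setdefault(wid, {"pool": "loyal", "mother_id": None, "weaned": False})
                if wid in sightings and rng.random() < config.calf_fraction:
                    calf_id = f"C{wid}-{year}"
                    add_whale_year(calf_id, year, loyal_mean, "calf")
                    if calf_id in sightings:
                        meta[calf_id] = {"pool": "calf", "mother_id": wid, "weaned": True}
                        calf_roster[calf_id] = float(np.clip(length / 45.0, 0.0, 0.9))

        for calf_id, p_ret in list(calf_roster.items()):
            first = min(d.year for d in sightings[calf_id])
            if year > first and rng.random() < p_ret:
                add_whale_year(calf_id, year, config.loyal_residency_mean, "calf")

        n_single = int(rng.poisson(config.single_visit_rate * excess))
        for j in range(n_single):
            wid = f"S{year}-{j:03d}"
            add_whale_year(wid, year, single_mean, "single")
            if wid in sightings:
                meta[wid] = {"pool": "single", "mother_id": None, "weaned": False}
                n_single_total += 1

    catalogue = [
        SightingHistory(
            whale_id=wid,
            sightings=tuple(dates),
            is_weaned_calf_first_year=meta[wid]["weaned"],
            mother_id=meta[wid]["mother_id"],
        )
        for wid, dates in sorted(sightings.items())
        if wid in meta
    ]
    cat_truth = {
        "pools": {wid: m["pool"] for wid, m in meta.items() if wid in sightings},
        "n_loyal_catalogued": sum(
            1 for wid in sightings if meta.get(wid, {}).get("pool") == "loyal"
        ),
        "n_single_catalogued": n_single_total,
        "n_calves_catalogued": sum(
            1 for wid in sightings if meta.get(wid, {}).get("pool") == "calf"
        ),
        "residency": residency_truth,
    }
    return catalogue, cat_truth


# ---------------------------------------------------------------------------
# stage 3: calls and noise

def _class_weights(mean_nn: float, config: SimulationConfig) -> dict[str, float]:
    """Distance-dependent class mixture (relative per-class rates).

    A logistic switch around ``knock_distance_threshold``: knocks
    dominate at short inter-individual distances, moans at long ones;
    sweeps are distance-neutral and rumbles rare.
    """
    if math.isnan(mean_nn):
        # lone whale: distance undefined; far-field mixture
        z = 1.0
    else:
        z = 1.0 / (1.0 + math.exp(-(mean_nn - config.knock_distance_threshold)
                                  / config.distance_mixture_scale))
    return {
        "class1_knock": 1.0 - z,
        "class2_sweep": 0.5,
        "class3_moan": z,
        "class4_rumble": 0.01,
    }


def simulate_call_log(
    config: SimulationConfig,
    snapshots: list[SocialSnapshot],
    rng: np.random.Generator | None = None,
    window_hours: float = 1.0,
) -> tuple[list[CallRecord], dict]:
    """Poisson call streams per snapshot hour.

    Per core class the count is Poisson(call_rate_base x class weight x
    whales x hours); motherese is emitted only when cow-calf pairs are
    present, at ``motherese_rate`` per pair-hour.
    """
    if rng is None:
        rng = config.rngs()["calls"]
    calls: list[CallRecord] = []
    weights_truth = []
    for snap in snapshots:
        if snap.timestamp is None:
            raise ValueError(f"snapshot {snap.transect_id} has no timestamp")
        n_whales = snap.whale_count
        if n_whales == 0:
            continue
        weights = _class_weights(snap.mean_nn_distance, config)
        weights_truth.append(
            {"transect_id": snap.transect_id, "mean_nn": snap.mean_nn_distance,
             **weights}
        )
        deployment = str(snap.timestamp.year)
        for cls, w in weights.items():
            lam = config.call_rate_base * w * n_whales * window_hours
            n_calls = int(rng.poisson(lam))
            for _ in range(n_calls):
                offset = rng.uniform(0.0, window_hours * 3600.0)
                calls.append(
                    CallRecord(
                        timestamp=snap.timestamp + dt.timedelta(seconds=float(offset)),
                        call_class=cls,
                        deployment_id=deployment,
                    )
                )
        if snap.n_pairs > 0:
            lam = config.motherese_rate * snap.n_pairs * window_hours
            for _ in range(int(rng.poisson(lam))):
                offset = rng.uniform(0.0, window_hours * 3600.0)
                calls.append(
                    CallRecord(
                        timestamp=snap.timestamp + dt.timedelta(seconds=float(offset)),
                        call_class="motherese",
                        deployment_id=deployment,
                    )
                )
    calls.sort(key=lambda c: c.timestamp)
    return calls, {"class_weights": weights_truth}


def simulate_noise(
    config: SimulationConfig,
    snapshots: list[SocialSnapshot],
    rng: np.random.Generator | None = None,
    window_hours: float = 1.0,
) -> pd.Series:
    """Per-minute ambient noise levels over the analyzed windows."""
    if rng is None:
        rng = config.rngs()["noise"]
    index = []
    for snap in snapshots:
        if snap.timestamp is None:
            continue
        for m in range(int(window_hours * 60)):
            index.append(snap.timestamp + dt.timedelta(minutes=m))
    values = rng.normal(config.noise_mean, config.noise_sd, size=len(index))
    return pd.Series(values, index=pd.DatetimeIndex(index), name="nl_db")


# ---------------------------------------------------------------------------
# full dataset

def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run all sub-generators under the master seed's substreams."""
    rngs = config.rngs()
    prey_truth, skeleton = simulate_prey_whale_dynamics(config, rngs["dynamics"])
    transects = simulate_locations(config, skeleton, rngs["locations"])
    catalogue, cat_truth = simulate_sighting_histories(
        config, transects, prey_truth, rngs["catalogue"]
    )
    acoustic_years = sorted({t.year for t in transects})[-config.acoustic_years:]
    snapshots = [
        social_context(
            list(t.units),
            transect_id=t.transect_id,
            timestamp=dt.datetime.combine(t.date, dt.time(hour=10)),
            bay_label="bay",
        )
        for t in transects
        if t.year in acoustic_years
    ]
    calls, call_truth = simulate_call_log(config, snapshots, rngs["calls"])
    noise = simulate_noise(config, snapshots, rngs["noise"])
    truth = {
        "config": asdict(config),
        **prey_truth,
        **cat_truth,
        **call_truth,
        "acoustic_years": acoustic_years,
    }
    return SyntheticDataset(
        config=config,
        transects=transects,
        catalogue=catalogue,
        snapshots=snapshots,
        calls=calls,
        noise=noise,
        truth=truth,
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write transects/catalogue/calls/noise CSVs plus truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["transects"] = outdir / "transects.csv"
    transects_to_frame(dataset.transects).to_csv(paths["transects"], index=False)
    paths["catalogue"] = outdir / "catalogue.csv"
    catalogue_to_frame(dataset.catalogue).to_csv(paths["catalogue"], index=False)
    paths["calls"] = outdir / "calls.csv"
    pd.DataFrame(
        [
            {
                "timestamp": c.timestamp.isoformat(),
                "call_class": c.call_class,
                "deployment_id": c.deployment_id,
            }
            for c in dataset.calls
        ],
        columns=["timestamp", "call_class", "deployment_id"],
    ).to_csv(paths["calls"], index=False)
    paths["noise"] = outdir / "noise.csv"
    noise_df = dataset.noise.rename_axis("timestamp").reset_index()
    noise_df["timestamp"] = noise_df["timestamp"].map(lambda t: t.isoformat())
    noise_df.to_csv(paths["noise"], index=False)
    paths["truth"] = outdir / "truth.json"
    paths["truth"].write_text(json.dumps(dataset.truth, indent=1, default=str))
    return paths
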
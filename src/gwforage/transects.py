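"""Per-season foraging-intensity summaries from line-transect survey records.

A transect survey counts every foraging gray whale along a fixed route.
Whales are recorded as individuals, groups (all members sharing one
location), or cow-calf pairs.  A cow-calf pair contributes exactly one
whale to the count; groups contribute their group size.  Seasons run from
late May to early September, and each season is summarized by its mean and
maximum whales per transect, the peak date (days elapsed from the season
start), and the skewness/kurtosis of the within-season count series, which
describe how foraging pressure is distributed around the peak.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WhaleObservation",
    "TransectRecord",
    "AnnualSummary",
    "SEASON_START",
    "SEASON_END",
    "season_day",
    "summarize_year",
    "summarize_seasons",
    "classify_years",
    "transects_to_frame",
    "frame_to_transects",
]

#: Default season window (month, day): surveys run 24 May – 6 September.
SEASON_START = (5, 24)
SEASON_END = (9, 6)

_UNIT_TYPES = frozenset({"individual", "group", "cow_calf"})


@dataclass(frozen=True)
class WhaleObservation:
    """A single foraging unit located on a transect.

    ``count_contribution`` implements the survey counting rule: a group
    contributes its size, an individual contributes 1, and a cow-calf pair
    is counted as one foraging whale.
    """

    timestamp: dt.datetime
    lat: float
    lon: float
    unit_type: str = "individual"
    group_size: int = 1

    def __post_init__(self) -> None:
        if self.unit_type not in _UNIT_TYPES:
            raise ValueError(f"unknown unit_type {self.unit_type!r}")
        if self.group_size < 1:
            raise ValueError("group_size must be >= 1")

    @property
    def count_contribution(self) -> int:
        if self.unit_type == "group":
            return int(self.group_size)
        return 1


@dataclass(frozen=True)
class TransectRecord:
    """One survey pass: date, completion flag and the observed units."""

    transect_id: str
    date: dt.date
    completed: bool = True
    units: tuple[WhaleObservation, ...] = field(default_factory=tuple)

    @property
    def whale_count(self) -> int:
        return sum(u.count_contribution for u in self.units)

    @property
    def year(self) -> int:
        return self.date.year


@dataclass
class AnnualSummary:
    """Season-level foraging-intensity statistics.

    ``peak_date_days`` counts days elapsed from the season start
    (24 May = day 0).  ``skewness``/``excess_kurtosis`` are the adjusted
    Fisher-Pearson sample estimators; they are NaN when undefined
    (fewer than 3 transects or fewer than 2 distinct counts).
    ``classification`` is assigned by :func:`classify_years`.
    """

    year: int
    n_transects: int
    mean_whales: float
    max_whales: int
    peak_date_days: int
    skewness: float
    excess_kurtosis: float
    raw_kurtosis: float
    classification: str | None = None

    def as_dict(self) -> dict:
        return {
            "year": self.year,
            "n_transects": self.n_transects,
            "mean_whales": self.mean_whales,
            "max_whales": self.max_whales,
            "peak_date_days": self.peak_date_days,
            "skewness": self.skewness,
            "excess_kurtosis": self.excess_kurtosis,
            "raw_kurtosis": self.raw_kurtosis,
            "classification": self.classification,
        }


def season_day(date: dt.date, season_start: tuple[int, int] = SEASON_START) -> int:
    """Days elapsed from the season start of ``date``'s year (start = day 0)."""
    start = dt.date(date.year, *season_start)
    return (date - start).days


def summarize_year(
    transects: list[TransectRecord],
    season_start: tuple[int, int] = SEASON_START,
) -> AnnualSummary:
    """Summarize one season of transects.

    The mean is taken over *all* transects, zero-whale passes included,
    so it is whales per completed survey.  The peak date is the date of
    the maximum count, broken to the earliest date on ties.
    """
    if not transects:
        raise ValueError("summarize_year requires at least one transect")
    years = {t.year for t in transects}
    if len(years) > 1:
        raise ValueError(f"transects span multiple years: {sorted(years)}")
    (year,) = years

    ordered = sorted(transects, key=lambda t: t.date)
    counts = np.array([t.whale_count for t in ordered], dtype=float)
    peak_idx = int(np.argmax(counts))  # argmax takes the first maximum
    peak = season_day(ordered[peak_idx].date, season_start)

    if len(counts) >= 3 and len(set(counts)) >= 2:
        skew = float(stats.skew(counts, bias=False))
        exkurt = float(stats.kurtosis(counts, fisher=True, bias=False))
        rawkurt = exkurt + 3.0
    else:
        skew = exkurt = rawkurt = math.nan

    return AnnualSummary(
        year=year,
        n_transects=len(counts),
        mean_whales=float(counts.mean()),
        max_whales=int(counts.max()),
        peak_date_days=peak,
        skewness=skew,
        excess_kurtosis=exkurt,
        raw_kurtosis=rawkurt,
    )


def summarize_seasons(
    transects: list[TransectRecord],
    season_start: tuple[int, int] = SEASON_START,
) -> list[AnnualSummary]:
    """Group transects by year, summarize each season, and classify years."""
    by_year: dict[int, list[TransectRecord]] = {}
    for t in transects:
        by_year.setdefault(t.year, []).append(t)
    summaries = [
        summarize_year(by_year[y], season_start) for y in sorted(by_year)
    ]
    return classify_years(summaries)


def global_mean_whales(summaries: list[AnnualSummary]) -> float:
    """Grand mean whales/survey over all transects of all years.

    Computed as the transect-weighted mean of the yearly means, which
    equals the mean over the pooled transect counts.
    """
    n = sum(s.n_transects for s in summaries)
    if n == 0:
        raise ValueError("no transects")
    return sum(s.mean_whales * s.n_transects for s in summaries) / n


def classify_years(summaries: list[AnnualSummary]) -> list[AnnualSummary]:
    """Label each season high/low against the all-years global mean.

    A year is "high" when its mean whales/transect is strictly above the
    global mean; a mean exactly equal to the global mean is "low".
    Idempotent: re-classifying the output changes nothing.
    """
    if not summaries:
        return []
    gmean = global_mean_whales(summaries)
    return [
        replace(s, classification="high" if s.mean_whales > gmean else "low")
        for s in summaries
    ]


# ---------------------------------------------------------------------------
# tabular interchange (transects.csv dialect)

def transects_to_frame(transects: list[TransectRecord]) -> pd.DataFrame:
    """Flatten records to the transects.csv layout (one row per unit).

    Zero-whale transects are kept as a single row with unit_type ``none``
    and group_size 0, so the survey itself stays on record.
    """
    rows = []
    for t in sorted(transects, key=lambda t: t.date):
        if not t.units:
            rows.append(
                {
                    "transect_id": t.transect_id,
                    "date": t.date.isoformat(),
                    "completed": t.completed,
                    "unit_id": "",
                    "unit_type": "none",
                    "group_size": 0,
                    "lat": math.nan,
                    "lon": math.nan,
                }
            )
            continue
        for i, u in enumerate(t.units):
            rows.append(
                {
                    "transect_id": t.transect_id,
                    "date": t.date.isoformat(),
                    "completed": t.completed,
                    "unit_id": f"{t.transect_id}-u{i:03d}",
                    "unit_type": u.unit_type,
                    "group_size": u.group_size,
                    "lat": u.lat,
                    "lon": u.lon,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "transect_id", "date", "completed", "unit_id",
            "unit_type", "group_size", "lat", "lon",
        ],
    )


def frame_to_transects(frame: pd.DataFrame) -> list[TransectRecord]:
    """Rebuild TransectRecord objects from the transects.csv layout."""
    records = []
    for (tid, date_s), grp in frame.groupby(["transect_id", "date"], sort=True):
        date = dt.date.fromisoformat(str(date_s))
        completed = bool(grp["completed"].iloc[0])
        units = []
        for _, row in grp.iterrows():
            if row["unit_type"] == "none":
                continue
            units.append(
                WhaleObservation(
                    timestamp=dt.datetime.combine(date, dt.time(hour=10)),
                    lat=float(row["lat"]),
                    lon=float(row["lon"]),
                    unit_type=str(row["unit_type"]),
                    group_size=int(row["group_size"]),
                )
            )
        records.append(
            TransectRecord(
                transect_id=str(tid), date=date,
                completed=completed, units=tuple(units),
            )
        )
    records.sort(key=lambda t: t.date)
    return records
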
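"""Photo-identification mark-recapture bookkeeping.

Residency is the inclusive day span between a whale's first and last
sighting within a season (a single sighting gives 1 day).  A whale seen
in more than one summer is a "return" whale; one seen in exactly one
summer is a "single-visit" whale.  Category is assessed retrospectively
over the whole catalogue, so per-year return proportions count the
whales identified that year that are catalogue-wide returners.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .transects import AnnualSummary

__all__ = [
    "SightingHistory",
    "FidelitySummary",
    "compute_residency",
    "classify_catalogue",
    "fidelity_correlations",
    "catalogue_to_frame",
    "frame_to_catalogue",
]

logger = logging.getLogger(__name__)


@dataclass
class SightingHistory:
    """Capture history of one photo-identified whale."""

    whale_id: str
    sightings: tuple[dt.date, ...]
    is_weaned_calf_first_year: bool = False
    mother_id: str | None = None

    def __post_init__(self) -> None:
        if not self.sightings:
            raise ValueError(f"whale {self.whale_id}: empty sighting history")
        self.sightings = tuple(sorted(set(self.sightings)))

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(sorted({d.year for d in self.sightings}))

    @property
    def first_year(self) -> int:
        return self.sightings[0].year

    @property
    def n_return_years(self) -> int:
        """Years the whale was seen after (not counting) its first year."""
        return len(self.years) - 1

    @property
    def category(self) -> str:
        return "return" if len(self.years) >= 2 else "single_visit"


def compute_residency(history: SightingHistory, year: int) -> int:
    """Inclusive day span of the whale's sightings within ``year``.

    last - first + 1 days; a whale sighted once has residency 1 day.
    """
    days = [d for d in history.sightings if d.year == year]
    if not days:
        raise ValueError(f"whale {history.whale_id}: no sightings in {year}")
    return (max(days) - min(days)).days + 1


@dataclass
class FidelitySummary:
    """Catalogue-level site-fidelity tables.

    ``per_year`` has one row per year: total individuals identified,
    return/single-visit counts (catalogue-wide category) and the return
    proportion in percent, plus mean residency both including and
    excluding single-sighting (1-day) whales.  ``per_whale`` has one row
    per whale-year with the residency span.
    """

    per_year: pd.DataFrame
    per_whale: pd.DataFrame
    total_individuals: int = 0
    total_return: int = 0
    total_single_visit: int = 0

    @property
    def single_visit_proportion(self) -> float:
        """Percent of catalogued whales seen in exactly one summer."""
        return 100.0 * self.total_single_visit / self.total_individuals

    @property
    def return_proportion(self) -> float:
        return 100.0 * self.total_return / self.total_individuals


def _merge_duplicates(catalogue: list[SightingHistory]) -> list[SightingHistory]:
    seen: dict[str, SightingHistory] = {}
    for h in catalogue:
        if h.whale_id in seen:
            prev = seen[h.whale_id]
            logger.warning("duplicate whale_id %s: merging sightings", h.whale_id)
            seen[h.whale_id] = SightingHistory(
                whale_id=h.whale_id,
                sightings=prev.sightings + h.sightings,
                is_weaned_calf_first_year=prev.is_weaned_calf_first_year
                or h.is_weaned_calf_first_year,
                mother_id=prev.mother_id or h.mother_id,
            )
        else:
            seen[h.whale_id] = h
    return list(seen.values())


def classify_catalogue(catalogue: list[SightingHistory]) -> FidelitySummary:
    """Per-year and per-whale fidelity tables from sighting histories."""
    catalogue = _merge_duplicates(catalogue)
    whale_rows = []
    for h in catalogue:
        for year in h.years:
            whale_rows.append(
                {
                    "whale_id": h.whale_id,
                    "year": year,
                    "residency_days": compute_residency(h, year),
                    "n_sightings": sum(1 for d in h.sightings if d.year == year),
                    "category": h.category,
                    "n_return_years": h.n_return_years,
                    "first_year": h.first_year,
                }
            )
    per_whale = pd.DataFrame(
        whale_rows,
        columns=[
            "whale_id", "year", "residency_days", "n_sightings",
            "category", "n_return_years", "first_year",
        ],
    )

    year_rows = []
    if not per_whale.empty:
        for year, grp in per_whale.groupby("year"):
            total = len(grp)
            ret = int((grp["category"] == "return").sum())
            multi = grp.loc[grp["n_sightings"] > 1, "residency_days"]
            year_rows.append(
                {
                    "year": int(year),
                    "total_individuals": total,
                    "return_count": ret,
                    "single_visit_count": total - ret,
                    "return_proportion": 100.0 * ret / total,
                    "mean_residency_days": float(grp["residency_days"].mean()),
                    "mean_residency_days_multi": float(multi.mean()) if len(multi) else np.nan,
                }
            )
    per_year = pd.DataFrame(
        year_rows,
        columns=[
            "year", "total_individuals", "return_count", "single_visit_count",
            "return_proportion", "mean_residency_days", "mean_residency_days_multi",
        ],
    )

    n_return = sum(1 for h in catalogue if h.category == "return")
    return FidelitySummary(
        per_year=per_year,
        per_whale=per_whale,
        total_individuals=len(catalogue),
        total_return=n_return,
        total_single_visit=len(catalogue) - n_return,
    )


#: metric pairs correlated in the fidelity analysis:
#: (left column, right column, label)
_DEFAULT_PAIRS = [
    ("mean_residency_days", "mean_whales", "residency_vs_mean_whales"),
    ("return_count", "total_individuals", "return_vs_total"),
    ("single_visit_count", "total_individuals", "single_vs_total"),
    ("return_proportion", "total_individuals", "proportion_vs_total"),
    ("total_individuals", "mean_whales", "total_vs_mean_whales"),
]


def fidelity_correlations(
    summary: FidelitySummary,
    annual: list[AnnualSummary],
    pairs: list[tuple[str, str, str]] | None = None,
) -> pd.DataFrame:
    """Spearman rank correlations between fidelity and intensity metrics.

    Joins the per-year fidelity table with the annual transect summaries
    on year and reports rs with two-sided p for each metric pair.
    Requires at least 4 overlapping years; pairs with fewer are flagged.
    """
    annual_df = pd.DataFrame(
        [{"year": s.year, "mean_whales": s.mean_whales, "max_whales": s.max_whales}
         for s in annual]
    )
    merged = summary.per_year.merge(annual_df, on="year", how="inner")
    if len(merged) < 4:
        raise ValueError(
            f"only {len(merged)} overlapping years; >=4 required for rank correlations"
        )
    rows = []
    for left, right, label in pairs or _DEFAULT_PAIRS:
        sub = merged[[left, right]].dropna()
        if len(sub) < 4:
            rows.append({"pair": label, "rs": np.nan, "p_value": np.nan,
                         "n_years": len(sub), "flag": "insufficient"})
            continue
        if sub[left].nunique() < 2 or sub[right].nunique() < 2:
            rows.append({"pair": label, "rs": np.nan, "p_value": np.nan,
                         "n_years": len(sub), "flag": "constant"})
            continue
        rs, p = stats.spearmanr(sub[left], sub[right])
        rows.append({"pair": label, "rs": float(rs), "p_value": float(p),
                     "n_years": len(sub), "flag": ""})
    return pd.DataFrame(rows, columns=["pair", "rs", "p_value", "n_years", "flag"])


# ---------------------------------------------------------------------------
# tabular interchange (catalogue.csv dialect: whale_id, date, ...)

def catalogue_to_frame(catalogue: list[SightingHistory]) -> pd.DataFrame:
    rows = []
    for h in sorted(catalogue, key=lambda h: h.whale_id):
        for d in h.sightings:
            rows.append(
                {
                    "whale_id": h.whale_id,
                    "date": d.isoformat(),
                    "is_weaned_calf_first_year": h.is_weaned_calf_first_year,
                    "mother_id": h.mother_id or "",
                }
            )
    return pd.DataFrame(
        rows, columns=["whale_id", "date", "is_weaned_calf_first_year", "mother_id"]
    )


def frame_to_catalogue(frame: pd.DataFrame) -> list[SightingHistory]:
    histories = []
    for wid, grp in frame.groupby("whale_id", sort=True):
        histories.append(
            SightingHistory(
                whale_id=str(wid),
                sightings=tuple(dt.date.fromisoformat(str(d)) for d in grp["date"]),
                is_weaned_calf_first_year=bool(grp["is_weaned_calf_first_year"].iloc[0]),
                mother_id=(str(grp["mother_id"].iloc[0]) or None),
            )
        )
    return histories
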
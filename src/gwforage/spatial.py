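"""Spatial-use statistics: weighted mean locations, monthly heat grids,
and per-transect nearest-neighbor social context.

Distances are straight-line great-circle (haversine) distances on WGS84,
reported in meters; at the 1-10 km scale of a foraging bay this matches
planar distance to well under 0.1% and avoids any projection choice.
Grouped whales share one location and enter the distance matrix as a
single unit, as do cow-calf pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import haversine_distances

from .transects import TransectRecord, WhaleObservation

__all__ = [
    "EARTH_RADIUS_M",
    "great_circle_m",
    "weighted_mean_location",
    "SocialSnapshot",
    "social_context",
    "HeatGrid",
    "monthly_heat_grid",
    "monthly_weighted_means",
]

EARTH_RADIUS_M = 6_371_000.0


def great_circle_m(coords_a: np.ndarray, coords_b: np.ndarray | None = None) -> np.ndarray:
    """Pairwise great-circle distances in meters.

    ``coords_a``/``coords_b`` are (n, 2) arrays of [lat, lon] in decimal
    degrees.  With one argument the full symmetric matrix is returned.
    """
    a = np.radians(np.atleast_2d(coords_a))
    b = a if coords_b is None else np.radians(np.atleast_2d(coords_b))
    return haversine_distances(a, b) * EARTH_RADIUS_M


def weighted_mean_location(observations: list[WhaleObservation]) -> tuple[float, float]:
    """Mean (lat, lon) weighted by each unit's whale count contribution."""
    if not observations:
        raise ValueError("no observations")
    w = np.array([o.count_contribution for o in observations], dtype=float)
    if w.sum() <= 0:
        raise ValueError("zero total weight")
    lat = float(np.average([o.lat for o in observations], weights=w))
    lon = float(np.average([o.lon for o in observations], weights=w))
    return lat, lon


@dataclass
class SocialSnapshot:
    """Spatial configuration of foraging units during one transect pass.

    The distance matrix is symmetric with zero diagonal; the mean
    nearest-neighbor distance is defined only when at least two units are
    present (a single whale in the bay has no inter-individual distance).
    Duplicate locations are allowed — two units in the same prey patch
    have distance 0 and are flagged via ``same_patch_pairs``.
    """

    transect_id: str
    timestamp: object = None
    bay_label: str = ""
    units: tuple[WhaleObservation, ...] = field(default_factory=tuple)
    distance_matrix: np.ndarray | None = None
    nn_distances: np.ndarray | None = None
    mean_nn_distance: float = math.nan
    n_units: int = 0
    n_groups: int = 0
    n_pairs: int = 0
    same_patch_pairs: int = 0

    @property
    def whale_count(self) -> int:
        return sum(u.count_contribution for u in self.units)


def social_context(
    units: list[WhaleObservation],
    transect_id: str = "",
    timestamp=None,
    bay_label: str = "",
) -> SocialSnapshot:
    """Build the inter-individual distance snapshot for one transect.

    Each individual, group or cow-calf pair is one unit; nearest-neighbor
    distance per unit is the minimum off-diagonal row entry of the
    great-circle distance matrix.
    """
    snap = SocialSnapshot(
        transect_id=transect_id,
        timestamp=timestamp,
        bay_label=bay_label,
        units=tuple(units),
        n_units=len(units),
        n_groups=sum(1 for u in units if u.unit_type == "group"),
        n_pairs=sum(1 for u in units if u.unit_type == "cow_calf"),
    )
    if not units:
        return snap
    coords = np.array([[u.lat, u.lon] for u in units], dtype=float)
    dmat = great_circle_m(coords)
    np.fill_diagonal(dmat, 0.0)
    snap.distance_matrix = dmat
    if len(units) >= 2:
        off = dmat + np.diag(np.full(len(units), np.inf))
        snap.nn_distances = off.min(axis=1)
        snap.mean_nn_distance = float(snap.nn_distances.mean())
        iu = np.triu_indices(len(units), k=1)
        snap.same_patch_pairs = int(np.sum(dmat[iu] < 1e-9))
    return snap


@dataclass
class HeatGrid:
    """Monthly whale-count grid with half-open cells.

    ``cells`` maps (row, col) indices — offsets from the bounding-box
    origin in units of ``cell_size`` degrees — to whale counts.  Points
    outside an explicit bounding box land in the ``overflow`` count so
    that cell counts always conserve the monthly whale total.
    """

    month: int
    cell_size: float
    origin: tuple[float, float]
    cells: dict[tuple[int, int], int]
    overflow: int
    weighted_mean: tuple[float, float]
    total_whales: int

    def to_geojson(self) -> dict:
        features = []
        o_lat, o_lon = self.origin
        for (i, j), count in sorted(self.cells.items()):
            lat0 = o_lat + i * self.cell_size
            lon0 = o_lon + j * self.cell_size
            ring = [
                [lon0, lat0],
                [lon0 + self.cell_size, lat0],
                [lon0 + self.cell_size, lat0 + self.cell_size],
                [lon0, lat0 + self.cell_size],
                [lon0, lat0],
            ]
            features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Polygon", "coordinates": [ring]},
                    "properties": {"month": self.month, "count": count},
                }
            )
        return {"type": "FeatureCollection", "features": features}


def monthly_heat_grid(
    observations: list[WhaleObservation],
    cell_size: float,
    month: int,
    bounds: tuple[float, float, float, float] | None = None,
) -> HeatGrid:
    """Bin one month's whale counts onto a half-open lat/lon grid.

    ``bounds`` is (lat_min, lon_min, lat_max, lon_max); when omitted it is
    the bounding box of the observations.  Cells are half-open [lo, hi) in
    both axes, so a point exactly on a boundary joins the higher cell.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    obs = [o for o in observations if o.timestamp.month == month]
    if not obs:
        return HeatGrid(month, cell_size, (0.0, 0.0), {}, 0, (math.nan, math.nan), 0)
    lats = np.array([o.lat for o in obs])
    lons = np.array([o.lon for o in obs])
    if bounds is None:
        bounds = (lats.min(), lons.min(), lats.max(), lons.max())
    lat_min, lon_min, lat_max, lon_max = bounds
    cells: dict[tuple[int, int], int] = {}
    overflow = 0
    for o in obs:
        inside = lat_min <= o.lat <= lat_max and lon_min <= o.lon <= lon_max
        if not inside:
            overflow += o.count_contribution
            continue
        # tiny nudge so a point representing an exact cell boundary lands
        # in the higher cell despite float rounding of (x - origin) / size
        i = int(math.floor((o.lat - lat_min) / cell_size + 1e-9))
        j = int(math.floor((o.lon - lon_min) / cell_size + 1e-9))
        cells[(i, j)] = cells.get((i, j), 0) + o.count_contribution
    return HeatGrid(
        month=month,
        cell_size=cell_size,
        origin=(lat_min, lon_min),
        cells=cells,
        overflow=overflow,
        weighted_mean=weighted_mean_location(obs),
        total_whales=sum(o.count_contribution for o in obs),
    )


def monthly_weighted_means(transects: list[TransectRecord]) -> pd.DataFrame:
    """Whale-count-weighted mean location per (year, month).

    Tracks the seasonal south-to-north drift of the foraging corpus.
    """
    rows = []
    by_ym: dict[tuple[int, int], list[WhaleObservation]] = {}
    for t in transects:
        for u in t.units:
            by_ym.setdefault((t.year, u.timestamp.month), []).append(u)
    for (year, month), obs in sorted(by_ym.items()):
        lat, lon = weighted_mean_location(obs)
        rows.append(
            {
                "year": year,
                "month": month,
                "lat": lat,
                "lon": lon,
                "n_whales": sum(o.count_contribution for o in obs),
            }
        )
    return pd.DataFrame(rows, columns=["year", "month", "lat", "lon", "n_whales"])
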
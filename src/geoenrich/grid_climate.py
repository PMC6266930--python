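"""Gridded climate lookups and day/month/year temporal averaging.

The source rasters are assumed to be pre-interpolated to a regular grid
(default 5 km spacing), so a query reads the nearest cell center without
further interpolation. Temporal averaging pools all grids of one variable
whose date falls in the civil-calendar day, month or year containing the
query date, skipping missing cells.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from datetime import date as Date
from pathlib import Path

import numpy as np

from .geo_core import GeoPoint, KM_PER_DEG, haversine_km_vec

logger = logging.getLogger(__name__)

GRANULARITIES = ("day", "month", "year")


@dataclass(frozen=True)
class ClimateGrid:
    """One variable on one date on a regular grid anchored at its SW corner.

    Cell centers sit on a lat/lon lattice: row i at origin.lat +
    i * spacing/111.195 degrees, column j at origin.lon +
    j * spacing/(111.195 * cos(origin.lat)) degrees. Missing cells are NaN.
    """

    variable: str
    date: Date
    origin: GeoPoint
    spacing_km: float
    values: np.ndarray

    def __post_init__(self) -> None:
        if not self.spacing_km > 0:
            raise ValueError("spacing_km must be > 0")
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("grid values must be a 2-D rectangle")
        object.__setattr__(self, "values", v)

    @property
    def cell_lats(self) -> np.ndarray:
        return self.origin.lat + np.arange(self.values.shape[0]) * self.spacing_km / KM_PER_DEG

    @property
    def cell_lons(self) -> np.ndarray:
        step = self.spacing_km / (KM_PER_DEG * math.cos(math.radians(self.origin.lat)))
        return self.origin.lon + np.arange(self.values.shape[1]) * step


def read_grid_file(path: str | Path) -> ClimateGrid:
    """Read the plain-text grid format: 5 header lines then value rows.

    Header lines: variable, ISO date, origin lat, origin lon, spacing_km.
    Missing values are written as ``NA``.
    """
    lines = Path(path).read_text().splitlines()
    variable = lines[0].strip()
    d = Date.fromisoformat(lines[1].strip())
    origin = GeoPoint(float(lines[2]), float(lines[3]))
    spacing = float(lines[4])
    rows = [
        [math.nan if tok == "NA" else float(tok) for tok in ln.split()]
        for ln in lines[5:]
        if ln.strip()
    ]
    return ClimateGrid(variable, d, origin, spacing, np.array(rows))


def write_grid_file(grid: ClimateGrid, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{grid.variable}\n{grid.date.isoformat()}\n")
        fh.write(f"{grid.origin.lat}\n{grid.origin.lon}\n{grid.spacing_km}\n")
        for row in grid.values:
            fh.write(" ".join("NA" if math.isnan(v) else repr(float(v)) for v in row) + "\n")


def lookup_value(grid: ClimateGrid, p: GeoPoint) -> float:
    """Value of the nearest cell center; NaN propagates if that cell is missing."""
    lats, lons = grid.cell_lats, grid.cell_lons
    half_lat = grid.spacing_km / KM_PER_DEG / 2.0
    half_lon = (lons[1] - lons[0]) / 2.0 if len(lons) > 1 else half_lat
    if not (lats[0] - half_lat <= p.lat <= lats[-1] + half_lat) or not (
        lons[0] - half_lon <= p.lon <= lons[-1] + half_lon
    ):
        raise ValueError(
            f"point ({p.lat}, {p.lon}) outside grid extent "
            f"lat [{lats[0]}, {lats[-1]}], lon [{lons[0]}, {lons[-1]}]"
        )
    lat_grid, lon_grid = np.meshgrid(lats, lons, indexing="ij")
    dist = haversine_km_vec(lat_grid, lon_grid, p)
    i, j = np.unravel_index(int(np.argmin(dist)), dist.shape)
    return float(grid.values[i, j])


def _in_period(d: Date, ref: Date, granularity: str) -> bool:
    if granularity == "day":
        return d == ref
    if granularity == "month":
        return d.year == ref.year and d.month == ref.month
    if granularity == "year":
        return d.year == ref.year
    raise ValueError(f"granularity must be one of {GRANULARITIES}, got {granularity!r}")


@dataclass(frozen=True)
class ClimateSummary:
    variable: str
    granularity: str
    mean: float
    n_days: int


def temporal_average(
    grids: list[ClimateGrid], p: GeoPoint, date: Date, granularity: str
) -> ClimateSummary:
    """Mean of nearest-cell values over all grids in the period containing `date`.

    Missing cells are skipped; if no non-missing value exists in the period the
    mean is NaN and a warning is logged.
    """
    in_period = [g for g in grids if _in_period(g.date, date, granularity)]
    if not in_period:
        raise ValueError(f"no grids within the {granularity} containing {date}")
    variable = in_period[0].variable
    vals = [lookup_value(g, p) for g in in_period]
    good = [v for v in vals if not math.isnan(v)]
    if not good:
        logger.warning(
            "no non-missing %s values in the %s containing %s", variable, granularity, date
        )
        return ClimateSummary(variable, granularity, math.nan, 0)
    return ClimateSummary(variable, granularity, float(np.mean(good)), len(good))
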
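"""Resolve a coordinate to an administrative (NUTS-like) region and attach
that region's wide statistics vector.

Regional statistics are reported per region, not per point, so every
coordinate inside the same polygon receives an identical feature vector —
there is no radius. Values are attached verbatim; normalising by region area
is an explicit opt-in because silent post-processing of third-party
statistics can introduce artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from shapely.geometry import Point, Polygon

from .geo_core import GeoPoint


@dataclass(frozen=True)
class RegionGazetteer:
    """Region polygons keyed by unique region_id; rings are simple (lat, lon)."""

    polygons: dict[str, Polygon]

    def __post_init__(self) -> None:
        for rid, poly in self.polygons.items():
            if not poly.is_valid:
                raise ValueError(f"region {rid!r} polygon is not simple/valid")

    @classmethod
    def from_csv(cls, path: str | Path) -> "RegionGazetteer":
        """Read polygons from CSV rows (region_id, vertex_index, lat, lon)."""
        df = pd.read_csv(path, dtype={"region_id": str})
        polys = {}
        for rid, grp in df.groupby("region_id", sort=True):
            grp = grp.sort_values("vertex_index")
            # shapely uses (x, y) = (lon, lat)
            polys[str(rid)] = Polygon(zip(grp["lon"], grp["lat"]))
        return cls(polys)


@dataclass(frozen=True)
class RegionalTable:
    """One wide numeric row per region_id; optional `area_km2` column."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("region_id index contains duplicates")

    @classmethod
    def from_csv(cls, path: str | Path) -> "RegionalTable":
        df = pd.read_csv(path, dtype={"region_id": str}).set_index("region_id")
        return cls(df)


def resolve_region(p: GeoPoint, gaz: RegionGazetteer) -> str:
    """Region whose polygon covers p (boundary inclusive).

    A point on a shared boundary is covered by several polygons; the
    lexicographically smallest region_id wins, deterministically.
    """
    if not gaz.polygons:
        raise ValueError("gazetteer is empty")
    pt = Point(p.lon, p.lat)
    hits = sorted(rid for rid, poly in gaz.polygons.items() if poly.covers(pt))
    if not hits:
        raise ValueError(f"unresolvable coordinate ({p.lat}, {p.lon}): no containing region")
    return hits[0]


def join_regional_features(
    region_id: str, table: RegionalTable, normalize_by_area: bool = False
) -> dict[str, float]:
    """All statistics of one region as `eurostat.`-prefixed named values.

    With ``normalize_by_area`` each value is divided by the region's
    ``area_km2`` and the column suffixed ``.per_km2``. Missing cells propagate
    unchanged (NaN).
    """
    if region_id not in table.data.index:
        raise ValueError(f"unknown region_id {region_id!r}")
    row = table.data.loc[region_id]
    area = None
    if normalize_by_area:
        if "area_km2" not in table.data.columns:
            raise ValueError("normalization requested but table has no area_km2 column")
        area = float(row["area_km2"])
    out: dict[str, float] = {}
    for col, val in row.items():
        if col == "area_km2":
            continue
        if area is not None:
            out[f"eurostat.{col}.per_km2"] = float(val) / area
        else:
            out[f"eurostat.{col}"] = float(val)
    return out
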
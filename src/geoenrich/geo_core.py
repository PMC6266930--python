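"""Projection, distance and bounding-box mathematics.

All enrichment backends share the same spherical-earth conventions defined
here: WGS84-style decimal-degree coordinates, spherical (Web-Mercator
compatible) earth of mean radius 6371.0088 km, and slippy-map global pixel
coordinates with the origin at the top-left (north-west) corner of the
projected world and y increasing southward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: Mean earth radius in km; consistent with Web-Mercator's spherical model.
EARTH_RADIUS_KM = 6371.0088

#: Ground kilometres per degree of latitude, 2*pi*R/360, rounded to the
#: constant used throughout (documented so tests are self-consistent).
KM_PER_DEG = 111.195

#: Latitude bound of the Web-Mercator projection, atan(sinh(pi)) in degrees.
MERCATOR_LAT_MAX = 85.05112878


def _normalize_lon(lon: float) -> float:
    """Map a longitude to the canonical interval [-180, 180)."""
    lon = (lon + 180.0) % 360.0 - 180.0
    # Python's % can return exactly 360.0 - eps rounding back to 180.0.
    return -180.0 if lon == 180.0 else lon


@dataclass(frozen=True)
class GeoPoint:
    """A WGS84 coordinate: latitude in [-90, 90], longitude in [-180, 180)."""

    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        if not math.isfinite(self.lon):
            raise ValueError(f"longitude {self.lon} is not finite")
        object.__setattr__(self, "lon", _normalize_lon(float(self.lon)))
        object.__setattr__(self, "lat", float(self.lat))


@dataclass(frozen=True)
class MercatorPixel:
    """Global Web-Mercator pixel coordinate at a zoom level.

    Origin top-left, y increases southward; valid range is the half-open
    square [0, tile_size * 2**zoom) in both axes.
    """

    x: float
    y: float
    zoom: int
    tile_size: int = 256

    def __post_init__(self) -> None:
        if self.zoom < 0 or int(self.zoom) != self.zoom:
            raise ValueError(f"zoom must be a non-negative integer, got {self.zoom}")
        world = self.tile_size * 2 ** self.zoom
        if not (0 <= self.x < world and 0 <= self.y < world):
            raise ValueError(
                f"pixel ({self.x}, {self.y}) outside world [0, {world}) at zoom {self.zoom}"
            )

    @property
    def world_size(self) -> int:
        return self.tile_size * 2 ** self.zoom


@dataclass(frozen=True)
class BoundingBox:
    """An axis-aligned lat/lon box; never crosses a pole or the antimeridian."""

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float

    def __post_init__(self) -> None:
        if self.lat_min > self.lat_max:
            raise ValueError("lat_min > lat_max")

    def contains(self, p: GeoPoint) -> bool:
        return (
            self.lat_min <= p.lat <= self.lat_max
            and self.lon_min <= p.lon <= self.lon_max
        )


@dataclass(frozen=True)
class RadiusSpec:
    """A ground-distance radius in kilometres."""

    radius_km: float

    def __post_init__(self) -> None:
        if not self.radius_km > 0:
            raise ValueError(f"radius_km must be positive, got {self.radius_km}")


def project_to_mercator(p: GeoPoint, zoom: int, tile_size: int = 256) -> MercatorPixel:
    """Project a coordinate to global Web-Mercator pixel coordinates.

    Spherical Mercator (EPSG:3857-style) with the slippy-map pixel
    convention: x grows eastward from lon -180, y grows southward from
    lat +85.05112878.
    """
    if abs(p.lat) > MERCATOR_LAT_MAX:
        raise ValueError(
            f"latitude {p.lat} beyond Web-Mercator bound +/-{MERCATOR_LAT_MAX}"
        )
    world = tile_size * 2 ** zoom
    x = (p.lon + 180.0) / 360.0 * world
    lat_rad = math.radians(p.lat)
    y = (1.0 - math.log(math.tan(lat_rad) + 1.0 / math.cos(lat_rad)) / math.pi) / 2.0 * world
    # Clamp boundary rounding so the result satisfies the half-open invariant.
    x = min(max(x, 0.0), math.nextafter(world, 0.0))
    y = min(max(y, 0.0), math.nextafter(world, 0.0))
    return MercatorPixel(x=x, y=y, zoom=zoom, tile_size=tile_size)


def pixel_to_geo(px: MercatorPixel) -> GeoPoint:
    """Invert :func:`project_to_mercator` for a global pixel coordinate."""
    world = px.world_size
    lon = px.x / world * 360.0 - 180.0
    n = math.pi * (1.0 - 2.0 * px.y / world)
    lat = math.degrees(math.atan(math.sinh(n)))
    return GeoPoint(lat=lat, lon=lon)


def haversine_km(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle ground distance in km on the R = 6371.0088 km sphere."""
    la1, lo1, la2, lo2 = map(math.radians, (a.lat, a.lon, b.lat, b.lon))
    s = (
        math.sin((la2 - la1) / 2.0) ** 2
        + math.cos(la1) * math.cos(la2) * math.sin((lo2 - lo1) / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(s)))


def haversine_km_vec(lat: np.ndarray, lon: np.ndarray, center: GeoPoint) -> np.ndarray:
    """Vectorised haversine distance of many (lat, lon) arrays to one point."""
    la1 = np.radians(np.asarray(lat, dtype=float))
    lo1 = np.radians(np.asarray(lon, dtype=float))
    la2 = math.radians(center.lat)
    lo2 = math.radians(center.lon)
    s = (
        np.sin((la2 - la1) / 2.0) ** 2
        + np.cos(la1) * math.cos(la2) * np.sin((lo2 - lo1) / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(s)))


def bounding_box_for_radius(center: GeoPoint, r: RadiusSpec) -> BoundingBox:
    """Smallest practical lat/lon box guaranteed to contain the ground circle.

    The latitude half-width is r / 111.195 degrees. The longitude half-width
    uses the secant of the box edge latitude nearest the pole rather than the
    center latitude: a ground circle bulges in longitude slightly poleward of
    its center, so the center-latitude secant alone can shave off the circle's
    east/west extremes. Widening to the edge latitude restores the guarantee
    that no point within haversine distance r is excluded, which is what a
    bounding-box prefilter must provide.
    """
    if not -90.0 < center.lat < 90.0:
        raise ValueError("center latitude must lie strictly inside (-90, 90)")
    dlat = r.radius_km / KM_PER_DEG
    lat_min = center.lat - dlat
    lat_max = center.lat + dlat
    if lat_min <= -90.0 or lat_max >= 90.0:
        raise ValueError(
            f"bounding box for radius {r.radius_km} km at lat {center.lat} crosses a pole"
        )
    edge_lat = max(abs(lat_min), abs(lat_max))
    dlon = dlat / math.cos(math.radians(edge_lat))
    lon_min = center.lon - dlon
    lon_max = center.lon + dlon
    if lon_min < -180.0 or lon_max >= 180.0:
        raise ValueError(
            f"bounding box for radius {r.radius_km} km at lon {center.lon} "
            "crosses the antimeridian (wrap not supported)"
        )
    return BoundingBox(lat_min=lat_min, lat_max=lat_max, lon_min=lon_min, lon_max=lon_max)
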
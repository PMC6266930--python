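"""Land-use area fractions around a coordinate from raster map tiles.

A slippy-map tile pyramid renders the world in Web-Mercator projection, so a
pixel's ground area shrinks with cos^2(latitude). This module stitches the
tiles covering a ground radius around a query point, classifies pixels by
legend colors, and converts pixel counts into ground-area fractions with an
explicit latitudinal area correction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .geo_core import (
    GeoPoint,
    MercatorPixel,
    RadiusSpec,
    bounding_box_for_radius,
    haversine_km_vec,
    pixel_to_geo,
    project_to_mercator,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RasterTile:
    """One z/x/y map tile with an RGB pixel grid of shape (ts, ts, 3)."""

    zoom: int
    tile_x: int
    tile_y: int
    pixels: np.ndarray

    def __post_init__(self) -> None:
        n = 2 ** self.zoom
        if not (0 <= self.tile_x < n and 0 <= self.tile_y < n):
            raise ValueError(
                f"tile ({self.zoom}/{self.tile_x}/{self.tile_y}) invalid for zoom {self.zoom}"
            )
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[0] != px.shape[1] or px.shape[2] != 3:
            raise ValueError(f"pixel grid must be (ts, ts, 3), got {px.shape}")
        object.__setattr__(self, "pixels", px.astype(np.uint8))

    @property
    def tile_size(self) -> int:
        return self.pixels.shape[0]


@dataclass(frozen=True)
class LegendEntry:
    class_name: str
    rgb: tuple[int, int, int]
    tolerance: int = 0


@dataclass(frozen=True)
class LegendTable:
    """Ordered legend; on color-tolerance overlap the first entry wins."""

    entries: tuple[LegendEntry, ...]

    def __post_init__(self) -> None:
        names = [e.class_name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("legend class names must be unique")
        if any(e.tolerance < 0 for e in self.entries):
            raise ValueError("legend tolerances must be >= 0")

    @classmethod
    def from_csv(cls, path: str | Path) -> "LegendTable":
        df = pd.read_csv(path)
        entries = tuple(
            LegendEntry(str(r["class"]), (int(r["r"]), int(r["g"]), int(r["b"])),
                        int(r.get("tolerance", 0)))
            for _, r in df.iterrows()
        )
        return cls(entries)


@dataclass
class RegionRaster:
    """A stitched pixel crop around a center with geographic metadata.

    `row_lats` holds the latitude of each pixel-row center, `col_lons` the
    longitude of each pixel-column center, and `mask` flags pixels whose
    ground position lies within `radius_km` of `center` (or the full crop in
    square mode).
    """

    pixels: np.ndarray
    row_lats: np.ndarray
    col_lons: np.ndarray
    mask: np.ndarray
    center: GeoPoint
    radius_km: float
    zoom: int = field(default=0)
    pixel_origin: tuple[int, int] = field(default=(0, 0))  # global (x0, y0)
    tile_size: int = field(default=256)

    def edge_bounds(self) -> tuple[float, float, float, float]:
        """Exact (lat_min, lat_max, lon_min, lon_max) of the crop's pixel edges."""
        x0, y0 = self.pixel_origin
        h, w = self.pixels.shape[:2]
        nw = pixel_to_geo(MercatorPixel(x0, y0, self.zoom, self.tile_size))
        # south-east edge may coincide with the world edge; clamp inside
        se_x = min(x0 + w, self.tile_size * 2**self.zoom - 1e-9)
        se_y = min(y0 + h, self.tile_size * 2**self.zoom - 1e-9)
        se = pixel_to_geo(MercatorPixel(se_x, se_y, self.zoom, self.tile_size))
        return se.lat, nw.lat, nw.lon, se.lon


def load_tiles(root: str | Path) -> list[RasterTile]:
    """Read all tiles stored as <root>/<z>/<x>/<y>.png."""
    root = Path(root)
    tiles = []
    for png in sorted(root.glob("*/*/*.png")):
        z, x, y = int(png.parent.parent.name), int(png.parent.name), int(png.stem)
        arr = np.asarray(Image.open(png).convert("RGB"))
        tiles.append(RasterTile(zoom=z, tile_x=x, tile_y=y, pixels=arr))
    return tiles


def stitch_region(
    tiles: list[RasterTile],
    center: GeoPoint,
    r: RadiusSpec,
    region_shape: str = "circle",
) -> RegionRaster:
    """Crop the pixels covering the bounding box of (center, r) from tiles.

    All supplied tiles must share one zoom level; a missing tile within the
    footprint raises an error listing its (z, x, y) index.
    """
    if not tiles:
        raise ValueError("no tiles supplied")
    zooms = {t.zoom for t in tiles}
    if len(zooms) > 1:
        raise ValueError(f"tiles span multiple zoom levels: {sorted(zooms)}")
    zoom = zooms.pop()
    ts = tiles[0].tile_size
    by_index = {(t.tile_x, t.tile_y): t for t in tiles}

    box = bounding_box_for_radius(center, r)
    nw = project_to_mercator(GeoPoint(box.lat_max, box.lon_min), zoom, ts)
    se = project_to_mercator(GeoPoint(box.lat_min, box.lon_max), zoom, ts)
    x0, x1 = int(math.floor(nw.x)), int(math.ceil(se.x))
    y0, y1 = int(math.floor(nw.y)), int(math.ceil(se.y))

    tx0, tx1 = x0 // ts, (x1 - 1) // ts
    ty0, ty1 = y0 // ts, (y1 - 1) // ts
    missing = [
        (zoom, tx, ty)
        for tx in range(tx0, tx1 + 1)
        for ty in range(ty0, ty1 + 1)
        if (tx, ty) not in by_index
    ]
    if missing:
        raise ValueError(f"missing tiles in footprint: {missing}")

    crop = np.empty((y1 - y0, x1 - x0, 3), dtype=np.uint8)
    for tx in range(tx0, tx1 + 1):
        for ty in range(ty0, ty1 + 1):
            tile = by_index[(tx, ty)]
            gx0, gy0 = tx * ts, ty * ts
            sx0, sx1 = max(x0, gx0), min(x1, gx0 + ts)
            sy0, sy1 = max(y0, gy0), min(y1, gy0 + ts)
            crop[sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = tile.pixels[
                sy0 - gy0 : sy1 - gy0, sx0 - gx0 : sx1 - gx0
            ]

    row_lats = np.array(
        [pixel_to_geo(MercatorPixel(x0 + 0.5, y + 0.5, zoom, ts)).lat for y in range(y0, y1)]
    )
    col_lons = np.array(
        [pixel_to_geo(MercatorPixel(x + 0.5, y0 + 0.5, zoom, ts)).lon for x in range(x0, x1)]
    )

    if region_shape == "circle":
        lat_grid = np.broadcast_to(row_lats[:, None], crop.shape[:2])
        lon_grid = np.broadcast_to(col_lons[None, :], crop.shape[:2])
        dist = haversine_km_vec(lat_grid, lon_grid, center)
        mask = dist <= r.radius_km
    elif region_shape == "square":
        mask = np.ones(crop.shape[:2], dtype=bool)
    else:
        raise ValueError(f"region_shape must be 'circle' or 'square', got {region_shape!r}")

    return RegionRaster(
        pixels=crop, row_lats=row_lats, col_lons=col_lons, mask=mask,
        center=center, radius_km=r.radius_km, zoom=zoom,
        pixel_origin=(x0, y0), tile_size=ts,
    )


def classify_pixels(region: RegionRaster, legend: LegendTable) -> dict[str, np.ndarray]:
    """Assign each pixel to the first legend class matching within tolerance.

    Returns one boolean mask per class plus an ``"unclassified"`` mask; the
    masks partition the pixel grid.
    """
    if not legend.entries:
        raise ValueError("legend is empty")
    px = region.pixels.astype(np.int16)
    assigned = np.zeros(px.shape[:2], dtype=bool)
    masks: dict[str, np.ndarray] = {}
    overlap_logged = False
    for entry in legend.entries:
        ref = np.array(entry.rgb, dtype=np.int16)
        match = np.all(np.abs(px - ref) <= entry.tolerance, axis=2)
        if not overlap_logged and np.any(match & assigned):
            logger.info("legend color overlap; first-match-wins applied")
            overlap_logged = True
        masks[entry.class_name] = match & ~assigned
        assigned |= match
    masks["unclassified"] = ~assigned
    return masks


@dataclass(frozen=True)
class LandUseFractions:
    """Ground-area fraction per legend class plus the unclassified remainder."""

    fractions: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if any(not 0.0 <= f <= 1.0 + 1e-12 for f in self.fractions.values()):
            raise ValueError("fractions must lie in [0, 1]")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {total}")


def _row_weights(row_lats: np.ndarray, weighting: str) -> np.ndarray:
    c = np.cos(np.radians(row_lats))
    if weighting == "cos2":
        return c * c
    if weighting == "cos":
        return c
    if weighting == "none":
        return np.ones_like(c)
    raise ValueError(f"weighting must be 'cos2', 'cos' or 'none', got {weighting!r}")


def landuse_fractions(
    region: RegionRaster, legend: LegendTable, weighting: str = "cos2"
) -> LandUseFractions:
    """Ground-area fraction of each legend class within the region mask.

    Pixels are weighted per row by cos^2(latitude) by default: in Web-Mercator
    the ground length of a pixel edge scales with cos(lat) in both axes, so
    ground area per pixel scales with cos^2(lat). ``weighting="cos"`` applies
    only the single-axis correction; ``"none"`` counts raw pixels.
    """
    if not np.any(region.mask):
        raise ValueError("region mask is empty")
    masks = classify_pixels(region, legend)
    w = _row_weights(region.row_lats, weighting)
    wgrid = np.broadcast_to(w[:, None], region.mask.shape)
    denom = float(wgrid[region.mask].sum())
    fractions = {
        name: float(wgrid[m & region.mask].sum()) / denom for name, m in masks.items()
    }
    # Renormalise away float summation slack so the partition sums to 1.
    s = sum(fractions.values())
    fractions = {k: v / s for k, v in fractions.items()}
    return LandUseFractions(fractions=fractions)
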
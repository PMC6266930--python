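"""Tile stitching, color classification and area-weighted land-use fractions."""

import numpy as np
import pytest

from geoenrich.geo_core import GeoPoint, RadiusSpec, bounding_box_for_radius
from geoenrich.landuse_raster import (
    LegendEntry,
    LegendTable,
    RasterTile,
    classify_pixels,
    landuse_fractions,
    stitch_region,
)
from geoenrich.synthetic_fixtures import gen_map_tiles, tile_range_for_bbox

FOREST = (34, 139, 34)
WATER = (30, 144, 255)
MEADOW = (124, 252, 0)


def _tiles_for(center, radius_km, rectangles, zoom=13, background="meadow"):
    box = bounding_box_for_radius(center, RadiusSpec(radius_km))
    xs, ys = tile_range_for_bbox((box.lat_min, box.lat_max, box.lon_min, box.lon_max), zoom)
    return gen_map_tiles(rectangles, background, zoom, (xs, ys))


class TestStitchRegion:
    def test_single_tile_region_is_subgrid(self):
        center = GeoPoint(0.0, 0.0)
        world = _tiles_for(center, 1.0, [], zoom=13)
        region = stitch_region(world.tiles, center, RadiusSpec(1.0), region_shape="square")
        assert region.pixels.ndim == 3
        # uniform background world -> uniform crop
        assert np.all(region.pixels == np.array(MEADOW, dtype=np.uint8))

    def test_seams_match_source_tiles(self):
        center = GeoPoint(46.99, 9.99)
        world = _tiles_for(center, 3.0, [("forest", 46.9, 47.0, 9.9, 10.0)], zoom=12)
        region = stitch_region(world.tiles, center, RadiusSpec(3.0), region_shape="square")
        ts = world.tiles[0].tile_size
        by_index = {(t.tile_x, t.tile_y): t for t in world.tiles}
        x0, y0 = region.pixel_origin
        h, w = region.pixels.shape[:2]
        # every crop pixel equals the corresponding source-tile pixel
        for r in range(0, h, 37):
            for c in range(0, w, 37):
                gx, gy = x0 + c, y0 + r
                tile = by_index[(gx // ts, gy // ts)]
                assert np.array_equal(region.pixels[r, c], tile.pixels[gy % ts, gx % ts])

    def test_missing_tile_reported_with_index(self):
        center = GeoPoint(0.0, 0.0)
        world = _tiles_for(center, 2.0, [], zoom=13)
        removed = world.tiles[0]
        with pytest.raises(ValueError, match=rf"{removed.tile_x}, {removed.tile_y}"):
            stitch_region(world.tiles[1:], center, RadiusSpec(2.0))

    def test_mixed_zoom_rejected(self):
        t0 = RasterTile(1, 0, 0, np.zeros((8, 8, 3)))
        t1 = RasterTile(2, 0, 0, np.zeros((8, 8, 3)))
        with pytest.raises(ValueError, match="zoom"):
            stitch_region([t0, t1], GeoPoint(0, 0), RadiusSpec(1.0))

    def test_circular_mask_area_matches_circle(self):
        """Mask cardinality approximates pi r^2 / pixel ground area at the equator."""
        center = GeoPoint(0.0, 0.0)
        radius = 2.0
        world = _tiles_for(center, radius, [], zoom=14)
        region = stitch_region(world.tiles, center, RadiusSpec(radius))
        # pixel ground size at equator for zoom 14
        km_per_px = 2 * np.pi * 6371.0088 / (256 * 2**14)
        expected = np.pi * radius**2 / km_per_px**2
        assert region.mask.sum() == pytest.approx(expected, rel=0.02)


class TestClassifyPixels:
    def test_uniform_region_fully_classified(self):
        center = GeoPoint(10.0, 10.0)
        world = _tiles_for(center, 1.0, [("forest", 9.0, 11.0, 9.0, 11.0)])
        region = stitch_region(world.tiles, center, RadiusSpec(1.0))
        masks = classify_pixels(region, world.legend)
        assert masks["forest"].all()
        assert not masks["unclassified"].any()

    @staticmethod
    def _region_from_pixels(px):
        from geoenrich.landuse_raster import RegionRaster

        h, w = px.shape[:2]
        return RegionRaster(
            pixels=px, row_lats=np.zeros(h), col_lons=np.zeros(w),
            mask=np.ones((h, w), dtype=bool), center=GeoPoint(0, 0), radius_km=1.0,
        )

    def test_zero_tolerance_rejects_off_by_one(self):
        legend = LegendTable((LegendEntry("forest", FOREST, 0),))
        px = np.full((4, 4, 3), FOREST, dtype=np.uint8)
        px[0, 0, 1] += 1
        masks = classify_pixels(self._region_from_pixels(px), legend)
        assert masks["unclassified"].sum() == 1
        assert masks["unclassified"][0, 0]

    def test_matches_bruteforce_per_pixel_check(self, rng):
        legend = LegendTable(
            (
                LegendEntry("a", (10, 20, 30), 5),
                LegendEntry("b", (12, 22, 32), 5),  # overlaps a; first match wins
                LegendEntry("c", (200, 10, 10), 0),
            )
        )
        px = rng.integers(0, 40, size=(16, 16, 3)).astype(np.uint8)
        masks = classify_pixels(self._region_from_pixels(px), legend)
        for r in range(16):
            for c in range(16):
                expected = "unclassified"
                for e in legend.entries:
                    if all(abs(int(px[r, c, k]) - e.rgb[k]) <= e.tolerance for k in range(3)):
                        expected = e.class_name
                        break
                assert masks[expected][r, c]


class TestLandUseFractions:
    def test_single_class_region_is_one_anywhere(self):
        for lat in (0.0, 60.0):
            center = GeoPoint(lat, 10.0)
            world = _tiles_for(center, 1.0, [("forest", lat - 1, lat + 1, 9.0, 11.0)])
            region = stitch_region(world.tiles, center, RadiusSpec(1.0))
            frac = landuse_fractions(region, world.legend)
            assert frac.fractions["forest"] == pytest.approx(1.0, abs=1e-12)

    def test_fractions_sum_to_one(self, rng):
        legend = LegendTable((LegendEntry("a", (10, 20, 30), 30), LegendEntry("b", (200, 10, 10), 40)))
        px = rng.integers(0, 255, size=(32, 32, 3)).astype(np.uint8)
        region = TestClassifyPixels._region_from_pixels(px)
        region.row_lats[:] = np.linspace(39.9, 40.1, 32)  # non-uniform weights
        frac = landuse_fractions(region, legend)
        assert sum(frac.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_equator_half_split_is_half(self):
        center = GeoPoint(0.0, 10.0)
        world = _tiles_for(center, 1.0, [("forest", -1.0, 0.0, 9.0, 11.0)], zoom=14)
        region = stitch_region(world.tiles, center, RadiusSpec(1.0), region_shape="square")
        # crop to a vertically symmetric window around the equator row
        frac = landuse_fractions(region, world.legend)
        truth = world.truth_fractions(*region.edge_bounds())
        assert frac.fractions["forest"] == pytest.approx(truth["forest"], abs=0.01)
        assert truth["forest"] == pytest.approx(0.5, abs=0.05)

    def test_equator_weighted_equals_unweighted(self):
        center = GeoPoint(0.0, 10.0)
        world = _tiles_for(center, 1.0, [("forest", -1.0, 0.0, 9.0, 11.0)], zoom=14)
        region = stitch_region(world.tiles, center, RadiusSpec(1.0))
        w = landuse_fractions(region, world.legend, weighting="cos2").fractions
        u = landuse_fractions(region, world.legend, weighting="none").fractions
        for k in w:
            assert w[k] == pytest.approx(u[k], abs=1e-6)

    @pytest.mark.parametrize("lat", [0.0, 47.0, 60.0])
    def test_matches_spherical_truth(self, lat):
        """Area fractions agree with the exact spherical ground-truth areas."""
        center = GeoPoint(lat, 10.0)
        world = _tiles_for(
            center, 2.0,
            [("forest", lat - 0.2, lat, 9.8, 10.2), ("water", lat, lat + 0.005, 9.8, 10.2)],
        )
        region = stitch_region(world.tiles, center, RadiusSpec(2.0), region_shape="square")
        frac = landuse_fractions(region, world.legend)
        truth = world.truth_fractions(*region.edge_bounds())
        for cls in ("forest", "water", "meadow"):
            assert frac.fractions[cls] == pytest.approx(truth[cls], abs=0.01)

    def test_latitude_weighting_shifts_halves_at_60_north(self):
        """At lat 60 a pixel-half split is not a ground-area half split."""
        center = GeoPoint(60.0, 10.0)
        world = _tiles_for(center, 30.0, [("forest", 60.0, 62.0, 8.0, 12.0)], zoom=10)
        region = stitch_region(world.tiles, center, RadiusSpec(30.0), region_shape="square")
        weighted = landuse_fractions(region, world.legend, weighting="cos2").fractions["forest"]
        raw = landuse_fractions(region, world.legend, weighting="none").fractions["forest"]
        truth = world.truth_fractions(*region.edge_bounds())["forest"]
        assert weighted == pytest.approx(truth, abs=0.01)
        assert abs(raw - truth) > abs(weighted - truth)

    def test_retiling_invariance(self):
        """The same world split into different tile grids yields identical fractions."""
        center = GeoPoint(20.0, 10.0)
        rects = [("forest", 19.8, 20.0, 9.8, 10.3)]
        frames = []
        world_small = _tiles_for(center, 2.0, rects, zoom=13)
        # re-tile: regenerate at same zoom but with padded tile range
        box = bounding_box_for_radius(center, RadiusSpec(2.0))
        xs, ys = tile_range_for_bbox((box.lat_min, box.lat_max, box.lon_min, box.lon_max), 13, pad=1)
        world_big = gen_map_tiles(rects, "meadow", 13, (xs, ys))
        for world in (world_small, world_big):
            region = stitch_region(world.tiles, center, RadiusSpec(2.0))
            frames.append(landuse_fractions(region, world.legend).fractions)
        assert frames[0] == frames[1]

    def test_monotone_in_painted_area(self):
        # the 2 km circle spans ~0.018 deg; grow the painted rectangle inside it
        center = GeoPoint(5.0, 5.0)
        fr = []
        for east in (5.000, 5.010):
            world = _tiles_for(center, 2.0, [("forest", 4.9, 5.1, 4.9, east)])
            region = stitch_region(world.tiles, center, RadiusSpec(2.0))
            fr.append(landuse_fractions(region, world.legend).fractions["forest"])
        assert fr[1] > fr[0]

    def test_empty_mask_rejected(self):
        tile = RasterTile(0, 0, 0, np.zeros((4, 4, 3)))
        region = stitch_region([tile], GeoPoint(0, 0), RadiusSpec(1.0), region_shape="square")
        region.mask[:] = False
        with pytest.raises(ValueError, match="mask"):
            landuse_fractions(region, LegendTable((LegendEntry("a", (1, 2, 3), 0),)))
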
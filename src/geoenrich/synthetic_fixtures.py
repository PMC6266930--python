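"""Seeded generators for every input class the package consumes.

Each generator is a pure function of its spec and seed and emits
machine-readable ground truth alongside the data (exact spherical class
areas for painted tiles, brute-force radius counts for point sets,
closed-form period means for climate grids, generating probabilities and
asymptotic indices for count tables, planted-feature identities for
regression tables). Oracle tests read truth only from here, never from the
modules under test.

The default preset mirrors the shape of an alpine-lakes showcase — a few
dozen geo-located samples enriched into a sparse, wide feature table — not
the statistics of any real landscape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date as Date
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .alpha_diversity import OtuTable
from .efs_regression import FeatureTable
from .geo_core import EARTH_RADIUS_KM, GeoPoint, MercatorPixel, pixel_to_geo
from .grid_climate import ClimateGrid, write_grid_file
from .landuse_raster import LegendEntry, LegendTable, RasterTile


@dataclass(frozen=True)
class FixtureSpec:
    """Sizes, rates and effect sizes for all generators ("austria-like"
    defaults: 39 instances, ~1,200 usable features, 5 planted effects)."""

    seed: int = 0
    n_instances: int = 39
    n_features: int = 1200
    n_planted: int = 5
    beta: float = 1.0
    noise_sd: float = 1.0
    zero_inflation: float = 0.30
    missing_rate: float = 0.002
    n_decoy_blocks: int = 8
    block_size: int = 6
    n_points: int = 500
    n_samples: int = 39
    n_taxa: int = 120
    otu_depth: int = 5000
    n_regions: int = 4

    def __post_init__(self) -> None:
        for rate in (self.zero_inflation, self.missing_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


# ---------------------------------------------------------------------------
# land-use tiles


def spherical_rect_area_km2(lat_min: float, lat_max: float, lon_min: float, lon_max: float) -> float:
    """Exact area of a lat/lon rectangle on the R = 6371.0088 km sphere."""
    return (
        EARTH_RADIUS_KM**2
        * math.radians(lon_max - lon_min)
        * (math.sin(math.radians(lat_max)) - math.sin(math.radians(lat_min)))
    )


@dataclass(frozen=True)
class PaintedWorld:
    """Tiles painted from geo-rectangles plus exact per-class truth.

    ``truth(bbox)`` returns the exact spherical ground-area fraction of every
    class within a query lat/lon box, from the painted rectangles — fully
    independent of any pixel counting.
    """

    tiles: list[RasterTile]
    legend: LegendTable
    rectangles: list[tuple[str, float, float, float, float]]  # class, lat0, lat1, lon0, lon1
    background: str

    def truth_fractions(self, lat_min, lat_max, lon_min, lon_max) -> dict[str, float]:
        total = spherical_rect_area_km2(lat_min, lat_max, lon_min, lon_max)
        out = {e.class_name: 0.0 for e in self.legend.entries}
        covered = 0.0
        # painted rectangles are disjoint by construction
        for cls, a0, a1, o0, o1 in self.rectangles:
            ia0, ia1 = max(a0, lat_min), min(a1, lat_max)
            io0, io1 = max(o0, lon_min), min(o1, lon_max)
            if ia0 < ia1 and io0 < io1:
                area = spherical_rect_area_km2(ia0, ia1, io0, io1)
                out[cls] += area / total
                covered += area / total
        out[self.background] += 1.0 - covered
        return out


def tile_range_for_bbox(
    bbox: tuple[float, float, float, float], zoom: int, pad: int = 0, tile_size: int = 256
) -> tuple[range, range]:
    """Slippy tile x/y index ranges covering a (lat_min, lat_max, lon_min,
    lon_max) box at a zoom level, optionally padded by whole tiles."""
    from .geo_core import project_to_mercator

    lat0, lat1, lon0, lon1 = bbox
    nw = project_to_mercator(GeoPoint(lat1, lon0), zoom, tile_size)
    se = project_to_mercator(GeoPoint(lat0, lon1), zoom, tile_size)
    tx0, tx1 = int(nw.x // tile_size), int(se.x // tile_size)
    ty0, ty1 = int(nw.y // tile_size), int(se.y // tile_size)
    n = 2**zoom
    return (
        range(max(0, tx0 - pad), min(n, tx1 + pad + 1)),
        range(max(0, ty0 - pad), min(n, ty1 + pad + 1)),
    )


DEFAULT_LEGEND_CLASSES = [
    # 20 land-cover classes with well-separated reference colors
    ("forest", (34, 139, 34)), ("meadow", (124, 252, 0)), ("water", (30, 144, 255)),
    ("residential", (190, 190, 190)), ("industrial", (130, 110, 160)),
    ("commercial", (238, 130, 238)), ("farmland", (240, 230, 140)),
    ("orchard", (154, 205, 50)), ("vineyard", (128, 0, 128)),
    ("quarry", (139, 137, 137)), ("cemetery", (85, 107, 47)),
    ("park", (0, 250, 154)), ("allotments", (189, 183, 107)),
    ("heath", (210, 180, 140)), ("scrub", (107, 142, 35)),
    ("wetland", (95, 158, 160)), ("beach", (255, 228, 181)),
    ("glacier", (240, 248, 255)), ("military", (178, 34, 34)),
    ("railway", (105, 105, 105)),
]


def default_legend(tolerance: int = 10) -> LegendTable:
    return LegendTable(
        tuple(LegendEntry(name, rgb, tolerance) for name, rgb in DEFAULT_LEGEND_CLASSES)
    )


def gen_map_tiles(
    rectangles: list[tuple[str, float, float, float, float]],
    background: str,
    zoom: int,
    tile_range: tuple[range, range],
    legend: LegendTable | None = None,
    tile_size: int = 256,
) -> PaintedWorld:
    """Paint axis-aligned geo-rectangles of legend colors onto slippy tiles.

    Each pixel takes the color of the rectangle containing its center, else
    the background class color. Painted rectangles must be disjoint so the
    analytic truth is additive.
    """
    legend = legend or default_legend()
    colors = {e.class_name: e.rgb for e in legend.entries}
    tiles = []
    xs, ys = tile_range
    for tx in xs:
        for ty in ys:
            px = np.empty((tile_size, tile_size, 3), dtype=np.uint8)
            row_lats = np.array(
                [
                    pixel_to_geo(MercatorPixel(tx * tile_size + 0.5,
                                               ty * tile_size + r + 0.5, zoom, tile_size)).lat
                    for r in range(tile_size)
                ]
            )
            col_lons = np.array(
                [
                    pixel_to_geo(MercatorPixel(tx * tile_size + c + 0.5,
                                               ty * tile_size + 0.5, zoom, tile_size)).lon
                    for c in range(tile_size)
                ]
            )
            px[:, :] = colors[background]
            lat_g = row_lats[:, None]
            lon_g = col_lons[None, :]
            for cls, a0, a1, o0, o1 in rectangles:
                inside = (lat_g >= a0) & (lat_g < a1) & (lon_g >= o0) & (lon_g < o1)
                px[inside] = colors[cls]
            tiles.append(RasterTile(zoom=zoom, tile_x=tx, tile_y=ty, pixels=px))
    return PaintedWorld(tiles=tiles, legend=legend, rectangles=rectangles, background=background)


def write_tiles(world: PaintedWorld, root: str | Path) -> None:
    root = Path(root)
    for t in world.tiles:
        d = root / str(t.zoom) / str(t.tile_x)
        d.mkdir(parents=True, exist_ok=True)
        Image.fromarray(t.pixels).save(d / f"{t.tile_y}.png")


def write_legend(legend: LegendTable, path: str | Path) -> None:
    rows = [
        {"class": e.class_name, "r": e.rgb[0], "g": e.rgb[1], "b": e.rgb[2],
         "tolerance": e.tolerance}
        for e in legend.entries
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# point events


def gen_points(
    spec: FixtureSpec,
    bbox: tuple[float, float, float, float],
    categories: tuple[str, ...],
    with_timestamps: bool = False,
    window_start: datetime | None = None,
    window_days: int = 7,
) -> pd.DataFrame:
    """Uniform random categorised points in a lat/lon box, as a CSV-ready frame.

    Truth counts for any (center, radius, category) query are obtained by
    brute force over this frame — see tests — so no truth is stored here.
    """
    rng = np.random.default_rng(spec.seed)
    lat0, lat1, lon0, lon1 = bbox
    n = spec.n_points
    df = pd.DataFrame(
        {
            "id": [f"p{i:05d}" for i in range(n)],
            "lat": rng.uniform(lat0, lat1, n),
            "lon": rng.uniform(lon0, lon1, n),
            "category": rng.choice(list(categories), n),
        }
    )
    if with_timestamps:
        start = window_start or datetime(2006, 8, 1)
        offsets = rng.uniform(0, window_days * 86400, n)
        df["timestamp"] = [
            (start + timedelta(seconds=float(s))).isoformat() for s in offsets
        ]
    return df


# ---------------------------------------------------------------------------
# climate grids


def gen_climate_grids(
    spec: FixtureSpec,
    variable: str,
    origin: GeoPoint,
    shape: tuple[int, int],
    start: Date,
    n_days: int,
    base: float = 10.0,
    lat_slope: float = 0.5,
    day_slope: float = 0.1,
    noise_sd: float = 0.0,
    spacing_km: float = 5.0,
) -> tuple[list[ClimateGrid], np.ndarray]:
    """Daily grid series value(i, j, d) = base + lat_slope*i + day_slope*d + noise.

    Returns the grids and the exact closed-form per-cell mean over the period
    (the noiseless component; with noise the sample mean approaches it at the
    usual 1/sqrt(n_days) rate).
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = shape
    ii = np.arange(rows)[:, None] * np.ones((1, cols))
    grids = []
    for d in range(n_days):
        vals = base + lat_slope * ii + day_slope * d
        if noise_sd > 0:
            vals = vals + rng.normal(0, noise_sd, size=vals.shape)
        grids.append(
            ClimateGrid(variable, start + timedelta(days=d), origin, spacing_km, vals)
        )
    closed_form_mean = base + lat_slope * ii + day_slope * (n_days - 1) / 2.0
    return grids, closed_form_mean


def write_climate_dir(grids: list[ClimateGrid], root: str | Path) -> None:
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    for g in grids:
        write_grid_file(g, root / f"{g.variable}_{g.date.isoformat()}.txt")


# ---------------------------------------------------------------------------
# regions


def gen_regions(
    spec: FixtureSpec,
    bbox: tuple[float, float, float, float],
    n_stats: int = 12,
    missing_rate: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A rectangular grid of regions plus a wide sparse statistics table.

    Returns (gazetteer CSV frame with region_id/vertex_index/lat/lon, wide
    table frame with region_id, area_km2 and `<theme>.<stat>` columns).
    Region (i, j) covers the (i, j) cell of an n x n split of the box, so a
    point's true region is computable in closed form.
    """
    rng = np.random.default_rng(spec.seed)
    lat0, lat1, lon0, lon1 = bbox
    n = spec.n_regions
    lat_edges = np.linspace(lat0, lat1, n + 1)
    lon_edges = np.linspace(lon0, lon1, n + 1)
    gaz_rows, stat_rows = [], []
    themes = ["agri", "demo", "econ", "edu", "labour", "transport"]
    for i in range(n):
        for j in range(n):
            rid = f"R{i}{j}"
            ring = [
                (lat_edges[i], lon_edges[j]),
                (lat_edges[i], lon_edges[j + 1]),
                (lat_edges[i + 1], lon_edges[j + 1]),
                (lat_edges[i + 1], lon_edges[j]),
            ]
            for k, (la, lo) in enumerate(ring):
                gaz_rows.append({"region_id": rid, "vertex_index": k, "lat": la, "lon": lo})
            row = {"region_id": rid,
                   "area_km2": spherical_rect_area_km2(lat_edges[i], lat_edges[i + 1],
                                                       lon_edges[j], lon_edges[j + 1])}
            for s in range(n_stats):
                theme = themes[s % len(themes)]
                val = float(np.round(rng.lognormal(3, 1), 3))
                if rng.uniform() < missing_rate:
                    val = np.nan
                row[f"{theme}.stat{s:02d}"] = val
            stat_rows.append(row)
    return pd.DataFrame(gaz_rows), pd.DataFrame(stat_rows)


# ---------------------------------------------------------------------------
# OTU tables


@dataclass(frozen=True)
class OtuTruth:
    probabilities: pd.DataFrame  # samples x taxa generating probabilities
    shannon: pd.Series
    simpson: pd.Series  # asymptotic 1 - sum p^2
    evenness: pd.Series


def gen_otu_table(spec: FixtureSpec, depth: int | None = None) -> tuple[OtuTable, OtuTruth]:
    """Lognormal-abundance communities sampled multinomially at fixed depth.

    Per sample, taxon probabilities are a normalised lognormal draw (the
    standard ecological abundance model); counts are one multinomial draw of
    `depth` reads. The generating probabilities and their analytic indices
    are returned as asymptotic truth.
    """
    rng = np.random.default_rng(spec.seed)
    depth = depth or spec.otu_depth
    samples = [f"S{i:03d}" for i in range(spec.n_samples)]
    taxa = [f"OTU{j:04d}" for j in range(spec.n_taxa)]
    probs = np.empty((spec.n_samples, spec.n_taxa))
    counts = np.empty((spec.n_samples, spec.n_taxa), dtype=np.int64)
    for i in range(spec.n_samples):
        raw = rng.lognormal(mean=0.0, sigma=1.5, size=spec.n_taxa)
        p = raw / raw.sum()
        probs[i] = p
        counts[i] = rng.multinomial(depth, p)
    pdf = pd.DataFrame(probs, index=samples, columns=taxa)
    h = pd.Series(-(probs * np.log(probs)).sum(axis=1), index=samples)
    lam = (probs**2).sum(axis=1)
    truth = OtuTruth(
        probabilities=pdf,
        shannon=h,
        simpson=pd.Series(1.0 - lam, index=samples),
        evenness=pd.Series((1.0 / lam) / spec.n_taxa, index=samples),
    )
    return OtuTable(pd.DataFrame(counts, index=samples, columns=taxa)), truth


# ---------------------------------------------------------------------------
# regression feature tables


@dataclass(frozen=True)
class PlantedTruth:
    planted: list[str]
    decoy_blocks: dict[str, list[str]]
    beta: float
    noise_sd: float


def gen_feature_table(spec: FixtureSpec) -> tuple[FeatureTable, PlantedTruth]:
    """Sparse feature table with planted predictive features.

    Layout: `planted000..` carry the signal (standardised effect `beta` each);
    `block00_f0..` form correlated decoy blocks sharing a latent factor
    (within-block |rho| > 0.7); the remainder `noise....` are independent.
    Zero-inflation is stratified — every inflated feature receives exactly
    round(rate * n) zeros at random positions — so a nominal rate below the
    prefilter cutoff cannot stochastically cross it. The target is built from
    the observed (post-inflation) planted values plus Gaussian noise, so the
    planted effects are genuinely present in the data the pipeline sees.
    Missingness is applied to non-planted features only (a feature with any
    missing value is by contract unusable downstream).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_instances
    ids = [f"L{i:03d}" for i in range(n)]
    n_zeros = int(round(spec.zero_inflation * n))

    def inflate(col: np.ndarray) -> np.ndarray:
        if n_zeros:
            col = col.copy()
            col[rng.choice(n, n_zeros, replace=False)] = 0.0
        return col

    cols: dict[str, np.ndarray] = {}
    planted = [f"planted{i:03d}" for i in range(spec.n_planted)]
    for name in planted:
        cols[name] = inflate(rng.normal(0, 1, n))

    decoys: dict[str, list[str]] = {}
    for b in range(spec.n_decoy_blocks):
        latent = rng.normal(0, 1, n)
        members = [f"block{b:02d}_f{m}" for m in range(spec.block_size)]
        decoys[members[0]] = members
        for name in members:
            # loading 0.95 puts the population within-block |rho| at 0.90,
            # keeping the block contract (> 0.7) true in sample too
            cols[name] = inflate(0.95 * latent + 0.31 * rng.normal(0, 1, n))

    n_noise = spec.n_features - len(cols)
    for m in range(max(0, n_noise)):
        cols[f"noise{m:05d}"] = inflate(rng.normal(0, 1, n))

    X = pd.DataFrame(cols, index=ids)
    signal = sum(spec.beta * X[name].to_numpy() for name in planted)
    y = pd.Series(signal + rng.normal(0, spec.noise_sd, n), index=ids, name="target")

    if spec.missing_rate > 0:
        non_planted = [c for c in X.columns if c not in planted]
        mask = rng.uniform(size=(n, len(non_planted))) < spec.missing_rate
        sub = X[non_planted].to_numpy()
        sub[mask] = np.nan
        X[non_planted] = sub

    truth = PlantedTruth(planted=planted, decoy_blocks=decoys,
                         beta=spec.beta, noise_sd=spec.noise_sd)
    return FeatureTable(X, y), truth


#: Workbench-scale regression fixture: five unit effects among 100 features
#: at 36 instances with mild noise — the scale at which the selection +
#: LOOCV + permutation machinery is comfortably identifiable.
def workbench_spec(seed: int) -> FixtureSpec:
    return FixtureSpec(
        seed=seed, n_instances=36, n_features=100, n_planted=5,
        zero_inflation=0.2, missing_rate=0.0, noise_sd=0.3,
        n_decoy_blocks=3, block_size=4,
    )


# ---------------------------------------------------------------------------
# whole-preset writer


def write_preset(outdir: str | Path, spec: FixtureSpec = FixtureSpec()) -> dict[str, Path]:
    """Write the full fixture set in the on-disk formats the CLI reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    center_lat, center_lon = 47.6, 13.4  # alpine-like latitude band
    bbox = (center_lat - 0.07, center_lat + 0.07, center_lon - 0.1, center_lon + 0.1)

    zoom = 12
    xs, ys = tile_range_for_bbox(bbox, zoom, pad=1)
    world = gen_map_tiles(
        rectangles=[
            ("forest", bbox[0] - 0.1, center_lat, bbox[2] - 0.1, bbox[3] + 0.1),
            ("water", center_lat, center_lat + 0.03, bbox[2] - 0.1, bbox[3] + 0.1),
        ],
        background="meadow",
        zoom=zoom,
        tile_range=(xs, ys),
    )
    write_tiles(world, outdir / "tiles")
    write_legend(world.legend, outdir / "legend.csv")
    paths["tiles"] = outdir / "tiles"
    paths["legend"] = outdir / "legend.csv"

    pois = gen_points(spec, bbox, ("craft", "leisure", "tourism", "transport", "urban"))
    pois.to_csv(outdir / "pois.csv", index=False)
    paths["pois"] = outdir / "pois.csv"

    tweets = gen_points(
        FixtureSpec(seed=spec.seed + 1, n_points=spec.n_points),
        bbox, ("tweet",), with_timestamps=True,
    )
    tweets.to_csv(outdir / "tweets.csv", index=False)
    paths["tweets"] = outdir / "tweets.csv"

    grids, _ = gen_climate_grids(
        spec, "temperature", GeoPoint(bbox[0], bbox[2]), (14, 14),
        Date(2006, 8, 1), 31, noise_sd=1.0,
    )
    write_climate_dir(grids, outdir / "climate")
    paths["climate"] = outdir / "climate"

    gaz, table = gen_regions(spec, bbox)
    gaz.to_csv(outdir / "regions.csv", index=False)
    table.to_csv(outdir / "regional_stats.csv", index=False)
    paths["regions"] = outdir / "regions.csv"
    paths["regional_stats"] = outdir / "regional_stats.csv"

    rng = np.random.default_rng(spec.seed + 2)
    coords = pd.DataFrame(
        {
            "id": [f"L{i:03d}" for i in range(spec.n_instances)],
            "lat": rng.uniform(bbox[0] + 0.02, bbox[1] - 0.02, spec.n_instances),
            "lon": rng.uniform(bbox[2] + 0.02, bbox[3] - 0.02, spec.n_instances),
            "date": "2006-08-15",
        }
    )
    coords.to_csv(outdir / "coords.csv", index=False)
    paths["coords"] = outdir / "coords.csv"

    otu, _ = gen_otu_table(spec)
    otu.counts.rename_axis("sample_id").to_csv(outdir / "otu_table.tsv", sep="\t")
    paths["otu"] = outdir / "otu_table.tsv"

    features, truth = gen_feature_table(spec)
    features.X.rename_axis("id").to_csv(outdir / "features.csv")
    features.y.rename_axis("id").to_csv(outdir / "target.csv")
    pd.Series(truth.planted, name="feature").to_csv(outdir / "planted.csv", index=False)
    paths["features"] = outdir / "features.csv"
    paths["target"] = outdir / "target.csv"
    return paths
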
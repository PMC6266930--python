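"""Per-coordinate orchestration of the enrichment backends and the
disk-buffered merge into one wide CSV.

Each enabled backend writes its output for all coordinates to its own
temporary partial CSV; the partials are then outer-joined on the coordinate
id in a streaming fashion (per-row seeks against byte-offset indexes, never
a whole table in memory) and removed. A backend failure on one coordinate
yields missing values for that row's columns plus a logged warning — one bad
database response must not abort a long run.
"""

from __future__ import annotations

import csv
import logging
import tempfile
from dataclasses import dataclass, field
from datetime import date as Date
from datetime import datetime, timedelta
from pathlib import Path

import pandas as pd

from .geo_core import GeoPoint, RadiusSpec
from . import grid_climate, landuse_raster, point_events, regional_stats

logger = logging.getLogger(__name__)

#: canonical module order; also the merged column-block order
MODULE_ORDER = ("landuse", "poi", "twitter", "climate", "eurostat")

_KNOWN_KEYS = {
    "modules", "radii", "date", "tiles", "legend", "region_shape", "weighting",
    "pois", "tweets", "climate_dir", "regions", "regional_stats",
    "normalize_by_area", "tweet_window_start", "tweet_window_days", "out", "log",
}
_RADIUS_MODULES = {"landuse", "poi", "twitter"}


@dataclass
class EnrichmentConfig:
    modules: list[str]
    radii: list[float] = field(default_factory=lambda: [1.0, 2.0, 5.0])
    date: Date | None = None
    tiles: str | None = None
    legend: str | None = None
    region_shape: str = "circle"
    weighting: str = "cos2"
    pois: str | None = None
    tweets: str | None = None
    climate_dir: str | None = None
    regions: str | None = None
    regional_stats: str | None = None
    normalize_by_area: bool = False
    tweet_window_start: datetime | None = None
    tweet_window_days: int = 7
    out: str | None = None
    log: str | None = None

    def __post_init__(self) -> None:
        if not self.modules:
            raise ValueError("at least one module must be enabled")
        unknown = [m for m in self.modules if m not in MODULE_ORDER]
        if unknown:
            raise ValueError(f"unknown modules {unknown}; available: {MODULE_ORDER}")
        if any(m in _RADIUS_MODULES for m in self.modules):
            if not self.radii or any(r <= 0 for r in self.radii):
                raise ValueError("radii must all be > 0 for radius-using modules")
        if "climate" in self.modules and self.date is None:
            raise ValueError("climate module requires a date")
        # deterministic module order regardless of config order
        self.modules = [m for m in MODULE_ORDER if m in self.modules]


def parse_config(path: str | Path) -> EnrichmentConfig:
    """Parse the key-value config file (``key = value`` lines, # comments).

    Unknown keys and duplicate keys are rejected with their line numbers.
    """
    seen: dict[str, int] = {}
    values: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        if key not in _KNOWN_KEYS:
            raise ValueError(f"line {lineno}: unknown key {key!r}")
        if key in seen:
            raise ValueError(
                f"duplicate key {key!r} on lines {seen[key]} and {lineno}"
            )
        seen[key] = lineno
        values[key] = val

    if "modules" not in values:
        raise ValueError("missing required key 'modules'")
    kwargs: dict = {"modules": [m.strip() for m in values["modules"].split(",") if m.strip()]}
    if "radii" in values:
        radii = [float(r) for r in values["radii"].split(",")]
        if any(r <= 0 for r in radii):
            raise ValueError(f"bad radius in {values['radii']!r}: radii must be > 0")
        kwargs["radii"] = radii
    if "date" in values:
        try:
            kwargs["date"] = Date.fromisoformat(values["date"])
        except ValueError as exc:
            raise ValueError(f"bad date {values['date']!r}: {exc}") from exc
    for key in ("tiles", "legend", "region_shape", "weighting", "pois", "tweets",
                "climate_dir", "regions", "regional_stats", "out", "log"):
        if key in values:
            kwargs[key] = values[key]
    if "normalize_by_area" in values:
        kwargs["normalize_by_area"] = values["normalize_by_area"].lower() in ("1", "true", "yes")
    if "tweet_window_start" in values:
        kwargs["tweet_window_start"] = datetime.fromisoformat(values["tweet_window_start"])
    if "tweet_window_days" in values:
        kwargs["tweet_window_days"] = int(values["tweet_window_days"])
    return EnrichmentConfig(**kwargs)


def read_coords(path: str | Path) -> list[tuple[str, GeoPoint, Date | None]]:
    """Read the coordinate list CSV with header id,lat,lon[,date]."""
    df = pd.read_csv(path, dtype={"id": str})
    out = []
    for row in df.itertuples(index=False):
        d = None
        if hasattr(row, "date") and isinstance(row.date, str) and row.date:
            d = Date.fromisoformat(row.date)
        out.append((row.id, GeoPoint(float(row.lat), float(row.lon)), d))
    return out


# ---------------------------------------------------------------------------
# per-module backends: each maps one coordinate -> {column: value}


def _landuse_columns(cfg: EnrichmentConfig, tiles, legend) -> "callable":
    def fn(point: GeoPoint, date: Date | None) -> dict[str, float]:
        out = {}
        for r in cfg.radii:
            region = landuse_raster.stitch_region(
                tiles, point, RadiusSpec(r), region_shape=cfg.region_shape
            )
            frac = landuse_raster.landuse_fractions(region, legend, weighting=cfg.weighting)
            for cls, v in frac.fractions.items():
                out[f"landuse.{cls}.{r:g}km"] = v
        return out

    return fn


def _poi_columns(cfg: EnrichmentConfig, points, categories) -> "callable":
    def fn(point: GeoPoint, date: Date | None) -> dict[str, float]:
        out = {}
        for r in cfg.radii:
            counts = point_events.count_in_radius(points, point, RadiusSpec(r), categories)
            for cat, v in counts.items():
                out[f"poi.{cat}.{r:g}km"] = v
        return out

    return fn


def _twitter_columns(cfg: EnrichmentConfig, points, window) -> "callable":
    def fn(point: GeoPoint, date: Date | None) -> dict[str, float]:
        return {
            f"twitter.count.{r:g}km": point_events.count_tweets(
                points, point, RadiusSpec(r), window
            )
            for r in cfg.radii
        }

    return fn


def _climate_columns(cfg: EnrichmentConfig, grids_by_var) -> "callable":
    def fn(point: GeoPoint, date: Date | None) -> dict[str, float]:
        d = date or cfg.date
        out = {}
        for var in sorted(grids_by_var):
            for gran in grid_climate.GRANULARITIES:
                summary = grid_climate.temporal_average(grids_by_var[var], point, d, gran)
                out[f"climate.{var}.{gran}"] = summary.mean
        return out

    return fn


def _eurostat_columns(cfg: EnrichmentConfig, gaz, table) -> "callable":
    def fn(point: GeoPoint, date: Date | None) -> dict[str, float]:
        rid = regional_stats.resolve_region(point, gaz)
        return regional_stats.join_regional_features(
            rid, table, normalize_by_area=cfg.normalize_by_area
        )

    return fn


def _build_backends(cfg: EnrichmentConfig) -> dict[str, "callable"]:
    backends: dict[str, "callable"] = {}
    if "landuse" in cfg.modules:
        tiles = landuse_raster.load_tiles(cfg.tiles)
        legend = landuse_raster.LegendTable.from_csv(cfg.legend)
        backends["landuse"] = _landuse_columns(cfg, tiles, legend)
    if "poi" in cfg.modules:
        points = point_events.load_points(cfg.pois)
        categories = tuple(sorted({p.category for p in points}))
        backends["poi"] = _poi_columns(cfg, points, categories)
    if "twitter" in cfg.modules:
        points = point_events.load_points(cfg.tweets)
        start = cfg.tweet_window_start or datetime(2006, 8, 1)
        window = point_events.TimeWindow(start, start + timedelta(days=cfg.tweet_window_days))
        backends["twitter"] = _twitter_columns(cfg, points, window)
    if "climate" in cfg.modules:
        grids_by_var: dict[str, list] = {}
        for f in sorted(Path(cfg.climate_dir).glob("*.txt")):
            g = grid_climate.read_grid_file(f)
            grids_by_var.setdefault(g.variable, []).append(g)
        backends["climate"] = _climate_columns(cfg, grids_by_var)
    if "eurostat" in cfg.modules:
        gaz = regional_stats.RegionGazetteer.from_csv(cfg.regions)
        table = regional_stats.RegionalTable.from_csv(cfg.regional_stats)
        backends["eurostat"] = _eurostat_columns(cfg, gaz, table)
    return backends


@dataclass
class EnrichedFeatureTable:
    """One row per input coordinate id; union of all module columns."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.columns.has_duplicates:
            raise ValueError("merged column names must be unique")


def enrich_coordinates(
    coords: list[tuple[str, GeoPoint, Date | None]],
    cfg: EnrichmentConfig,
    out_path: str | Path | None = None,
) -> EnrichedFeatureTable:
    """Run every enabled backend for every coordinate and merge the partials.

    Per-module outputs are buffered to temporary CSV files (module outputs
    can be far wider than memory for real backends) and removed after the
    merge. A backend exception on one coordinate leaves that row's module
    columns empty and logs a warning.
    """
    ids = [c[0] for c in coords]
    if not ids:
        raise ValueError("no coordinates supplied")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate coordinate ids")
    backends = _build_backends(cfg)

    with tempfile.TemporaryDirectory(prefix="geoenrich_") as tmp:
        partials = []
        for order, name in enumerate(cfg.modules):
            fn = backends[name]
            rows: list[dict[str, float]] = []
            columns: list[str] = []
            for cid, point, date in coords:
                try:
                    vals = fn(point, date)
                except Exception as exc:
                    logger.warning("module %s failed for id %s: %s", name, cid, exc)
                    vals = {}
                for col in vals:
                    if col not in columns:
                        columns.append(col)
                rows.append(vals)
            part = Path(tmp) / f"{order:02d}_{name}.csv"
            with open(part, "w", newline="") as fh:
                w = csv.writer(fh)
                w.writerow(["id", *columns])
                for cid, vals in zip(ids, rows):
                    w.writerow([cid] + [_fmt(vals.get(c)) for c in columns])
            partials.append(part)

        merged = Path(tmp) / "merged.csv"
        merge_outputs(partials, merged, cleanup=True)
        df = pd.read_csv(merged, dtype={"id": str}).set_index("id")

    if out_path is not None:
        _write_canonical_csv(df, out_path)
    return EnrichedFeatureTable(df)


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, float):
        if v != v:  # NaN
            return ""
        return repr(v)
    return str(v)


def _write_canonical_csv(df: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", *df.columns])
        for cid, row in df.iterrows():
            w.writerow([cid] + [_fmt(v if not pd.isna(v) else None) for v in row])


def merge_outputs(
    partials: list[str | Path], out_path: str | Path, cleanup: bool = False
) -> Path:
    """Streaming outer join of partial CSVs on the `id` column.

    Builds a byte-offset index per partial (id -> file position), then emits
    one output row at a time by seeking into each partial, so memory is
    bounded by a single row's width plus the id index — never by the table.
    Output row order: ids in order of first appearance across partials
    (partials in the given order). Duplicate non-id column names across
    partials are an error. With ``cleanup`` the partial files are removed.
    """
    partials = [Path(p) for p in partials]
    headers: list[list[str]] = []
    indexes: list[dict[str, int]] = []
    id_order: list[str] = []
    seen_ids: set[str] = set()
    all_cols: list[str] = []
    for p in partials:
        with open(p, "rb") as fh:
            header = fh.readline().decode().rstrip("\r\n").split(",")
            if header[0] != "id":
                raise ValueError(f"partial {p} lacks leading id column")
            dup = [c for c in header[1:] if c in all_cols]
            if dup:
                raise ValueError(f"conflicting duplicate columns across partials: {dup}")
            all_cols.extend(header[1:])
            index: dict[str, int] = {}
            pos = fh.tell()
            line = fh.readline()
            while line:
                rid = line.decode().split(",", 1)[0]
                index[rid] = pos
                if rid not in seen_ids:
                    seen_ids.add(rid)
                    id_order.append(rid)
                pos = fh.tell()
                line = fh.readline()
        headers.append(header)
        indexes.append(index)

    out_path = Path(out_path)
    handles = [open(p, "r", newline="") for p in partials]
    try:
        with open(out_path, "w", newline="") as out:
            w = csv.writer(out)
            w.writerow(["id", *all_cols])
            for rid in id_order:
                row = [rid]
                for fh, header, index in zip(handles, headers, indexes):
                    if rid in index:
                        fh.seek(index[rid])
                        vals = next(csv.reader([fh.readline()]))[1:]
                        # tolerate short rows (trailing missing)
                        vals += [""] * (len(header) - 1 - len(vals))
                        row.extend(vals)
                    else:
                        row.extend([""] * (len(header) - 1))
                w.writerow(row)
    finally:
        for fh in handles:
            fh.close()
    if cleanup:
        for p in partials:
            p.unlink()
    return out_path
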
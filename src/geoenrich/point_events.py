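"""Counting categorised point records (POIs) and time-stamped records (tweets)
within a ground radius of a query coordinate.

Counting uses a bounding-box prefilter followed by an exact haversine test;
the ball is closed (distance exactly r counts) and time windows are closed
intervals, so boundary records always count.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from pathlib import Path

import pandas as pd

from .geo_core import GeoPoint, RadiusSpec, bounding_box_for_radius, haversine_km

#: Default POI subfield vocabulary mirrored from the upstream map database's
#: commonly queried subfields.
DEFAULT_POI_SUBFIELDS = (
    "craft",
    "leisure",
    "powerplants",
    "special_buildings",
    "tourism",
    "transport",
    "urban",
)

#: Live-service pacing constraint of the tweet backend (75 queries / 15 min);
#: recorded as interface metadata, ignored by offline backends.
TWEET_QUERY_LIMIT = {"queries": 75, "per_minutes": 15}


@dataclass(frozen=True)
class PointRecord:
    id: str
    location: GeoPoint
    category: str
    timestamp: datetime | None = None


@dataclass(frozen=True)
class TimeWindow:
    start: datetime
    end: datetime

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("time window start > end")

    def contains(self, t: datetime) -> bool:
        return self.start <= t <= self.end


def load_points(path: str | Path) -> list[PointRecord]:
    """Read records from CSV with columns id,lat,lon,category[,timestamp]."""
    df = pd.read_csv(path, dtype={"id": str})
    records = []
    has_ts = "timestamp" in df.columns
    for row in df.itertuples(index=False):
        ts = None
        if has_ts and isinstance(row.timestamp, str) and row.timestamp:
            ts = datetime.fromisoformat(row.timestamp)
        records.append(
            PointRecord(
                id=row.id,
                location=GeoPoint(float(row.lat), float(row.lon)),
                category=str(row.category),
                timestamp=ts,
            )
        )
    return records


def _in_radius(p: PointRecord, center: GeoPoint, r: RadiusSpec, box) -> bool:
    return box.contains(p.location) and haversine_km(p.location, center) <= r.radius_km


def count_in_radius(
    points: list[PointRecord],
    center: GeoPoint,
    r: RadiusSpec,
    categories: tuple[str, ...],
) -> dict[str, int]:
    """Count records per category within the closed ground ball of radius r.

    Categories outside the declared vocabulary are ignored; the result always
    has one (possibly zero) entry per vocabulary category.
    """
    if not categories:
        raise ValueError("category vocabulary is empty")
    box = bounding_box_for_radius(center, r)
    counts = {c: 0 for c in categories}
    for p in points:
        if p.category in counts and _in_radius(p, center, r, box):
            counts[p.category] += 1
    return counts


def count_tweets(
    points: list[PointRecord],
    center: GeoPoint,
    r: RadiusSpec,
    window: TimeWindow,
) -> int:
    """Count time-stamped records inside the radius and the closed window."""
    box = bounding_box_for_radius(center, r)
    n = 0
    for p in points:
        if p.timestamp is None:
            raise ValueError(f"record {p.id!r} lacks a timestamp")
        if _in_radius(p, center, r, box) and window.contains(p.timestamp):
            n += 1
    return n
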
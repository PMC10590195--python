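"""GPS track handling: GPX parsing, haul cutting, swept distance and area.

A haul's GPS receiver logs a trackpoint every minute; observers additionally
note the vessel position every 15 min between net touchdown and retrieval.
The haul track is the GPX subtrack inside the onboard time window, and the
swept area is (track length) x (gear width).
"""

from __future__ import annotations

import logging
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Iterable, Sequence

import numpy as np

from .errors import EmptyHaulError, GPXParseError, InvalidInputError

__all__ = [
    "EARTH_RADIUS_KM",
    "GeoPoint",
    "GeoTrack",
    "haversine_km",
    "parse_gpx",
    "cut_haul_track",
    "swept_distance",
    "swept_area",
]

log = logging.getLogger(__name__)

#: Mean Earth radius for the spherical (haversine) distance model.
EARTH_RADIUS_KM = 6371.0

#: Gap between consecutive trackpoints above which a warning is logged.
GAP_WARNING_SECONDS = 600.0


@dataclass(frozen=True)
class GeoPoint:
    """A WGS84 position with UTC timestamp."""

    lat: float
    lon: float
    timestamp: datetime

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat <= 90.0):
            raise InvalidInputError(f"latitude {self.lat} outside [-90, 90]")
        if not (-180.0 <= self.lon <= 180.0):
            raise InvalidInputError(f"longitude {self.lon} outside [-180, 180]")


@dataclass(frozen=True)
class GeoTrack:
    """Time-ordered sequence of :class:`GeoPoint`."""

    points: tuple[GeoPoint, ...]
    source: str = "gpx"  # gpx | interpolated | synthetic

    def __post_init__(self) -> None:
        pts = tuple(self.points)
        object.__setattr__(self, "points", pts)
        for prev, cur in zip(pts, pts[1:]):
            if cur.timestamp <= prev.timestamp:
                raise InvalidInputError("track timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def start(self) -> datetime:
        return self.points[0].timestamp

    @property
    def end(self) -> datetime:
        return self.points[-1].timestamp

    @property
    def duration_minutes(self) -> float:
        if len(self.points) < 2:
            return 0.0
        return (self.end - self.start).total_seconds() / 60.0

    def to_geojson(self) -> dict:
        """GeoJSON LineString feature with a parallel ``timestamps`` property."""
        return {
            "type": "Feature",
            "geometry": {
                "type": "LineString",
                "coordinates": [[p.lon, p.lat] for p in self.points],
            },
            "properties": {
                "timestamps": [p.timestamp.isoformat() for p in self.points],
                "source": self.source,
            },
        }


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance (km) on a sphere of radius :data:`EARTH_RADIUS_KM`."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlmb = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlmb / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def _localname(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _parse_time(text: str) -> datetime:
    ts = datetime.fromisoformat(text.replace("Z", "+00:00"))
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc)


def parse_gpx(document: str) -> GeoTrack:
    """Parse a GPX 1.1 document into a :class:`GeoTrack`.

    All ``<trkseg>`` segments are concatenated in document order.  Every
    trackpoint must carry a ``<time>`` element; gaps longer than 10 min
    between consecutive points only log a warning.
    """
    try:
        root = ET.fromstring(document)
    except ET.ParseError as exc:
        raise GPXParseError(f"malformed GPX XML: {exc}") from exc

    points: list[GeoPoint] = []
    index = 0
    for elem in root.iter():
        if _localname(elem.tag) != "trkpt":
            continue
        try:
            lat = float(elem.attrib["lat"])
            lon = float(elem.attrib["lon"])
        except (KeyError, ValueError) as exc:
            raise GPXParseError(f"trackpoint {index}: bad lat/lon attributes") from exc
        time_el = next((c for c in elem if _localname(c.tag) == "time"), None)
        if time_el is None or not (time_el.text or "").strip():
            raise GPXParseError(f"trackpoint {index}: missing <time> element")
        try:
            ts = _parse_time(time_el.text.strip())
        except ValueError as exc:
            raise GPXParseError(f"trackpoint {index}: unparseable time {time_el.text!r}") from exc
        points.append(GeoPoint(lat=lat, lon=lon, timestamp=ts))
        index += 1

    if not points:
        raise GPXParseError("GPX document contains no trackpoints")

    for prev, cur in zip(points, points[1:]):
        gap = (cur.timestamp - prev.timestamp).total_seconds()
        if gap > GAP_WARNING_SECONDS:
            log.warning("GPX gap of %.1f min between consecutive trackpoints", gap / 60.0)

    return GeoTrack(points=tuple(points), source="gpx")


def cut_haul_track(track: GeoTrack, onboard: Sequence[GeoPoint]) -> GeoTrack:
    """Cut the subtrack inside the onboard-position time window.

    The window is [first onboard timestamp, last onboard timestamp], inclusive
    on both ends; onboard coordinates are not used for cutting.
    """
    if len(onboard) < 2:
        raise InvalidInputError("need at least 2 onboard positions to delimit a haul")
    t0 = onboard[0].timestamp
    t1 = onboard[-1].timestamp
    if t1 < t0:
        raise InvalidInputError("onboard positions end before they start")
    selected = tuple(p for p in track.points if t0 <= p.timestamp <= t1)
    if not selected:
        raise EmptyHaulError(
            f"onboard window [{t0.isoformat()}, {t1.isoformat()}] does not overlap the track"
        )
    return GeoTrack(points=selected, source=track.source)


def swept_distance(track: GeoTrack) -> float:
    """Track length in km: sum of haversine distances over consecutive points."""
    if len(track) == 0:
        raise InvalidInputError("track has no points")
    pts = track.points
    return float(
        sum(
            haversine_km(a.lat, a.lon, b.lat, b.lon)
            for a, b in zip(pts, pts[1:])
        )
    )


def swept_area(sd_km: float, gw_m: float) -> float:
    """Swept area (km²) = swept distance (km) x gear width (m) / 1000."""
    if not gw_m > 0:
        raise InvalidInputError(f"gear width must be positive, got {gw_m}")
    if sd_km < 0:
        raise InvalidInputError(f"swept distance must be >= 0, got {sd_km}")
    return sd_km * gw_m / 1000.0
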
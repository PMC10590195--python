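"""VMS fishing-effort pipeline.

Vessel Monitoring System pings arrive at >= 2 h cadence with position, speed
and course.  The pipeline: deduplicate and drop on-land points, code trips
(one vessel-day), densify each trip to a 10-min mesh, classify fishing
activity with a speed filter and a depth filter, compute fishing time
(10 min per fishing ping), split the day's landed weight and revenue equally
over the day's fishing pings, and rasterize effort / landings / revenue per
unit effort onto a km grid.

Pings travel through the pipeline as a pandas DataFrame with columns
``vessel_id, timestamp (UTC), lat, lon, speed`` (knots) and optionally
``course``; the pipeline adds ``origin``, ``trip_code``, ``is_fishing``.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import shapely

from .errors import ConfigError, InvalidInputError
from .geometry import EARTH_RADIUS_KM, haversine_km

__all__ = [
    "DEFAULT_SPEED_RANGE_KN",
    "DEFAULT_DEPTH_RANGE_M",
    "PING_INTERVAL_MIN",
    "GridSpec",
    "EffortGrid",
    "clean_pings",
    "assign_trip_codes",
    "interpolate_track_10min",
    "classify_fishing",
    "fishing_time",
    "allocate_landings",
    "rasterize_effort",
    "process_fleet",
]

log = logging.getLogger(__name__)

#: Trawling speed window (knots).  A convention, configurable: slower is
#: inactivity in port, faster is steaming.
DEFAULT_SPEED_RANGE_KN = (1.0, 4.5)

#: Legal trawling depth window (m) of the study area's continental margin.
DEFAULT_DEPTH_RANGE_M = (50.0, 1000.0)

#: Interpolated ping cadence in minutes.
PING_INTERVAL_MIN = 10

#: Daily legal fishing-time limit (hours); exceeding it logs a warning.
DAILY_FISHING_LIMIT_H = 12.0

KM_PER_NM = 1.852

_PING_COLUMNS = ["vessel_id", "timestamp", "lat", "lon", "speed", "course",
                 "origin", "trip_code", "is_fishing"]


def _ensure_columns(pings: pd.DataFrame) -> pd.DataFrame:
    df = pings.copy()
    if "course" not in df:
        df["course"] = np.nan
    if "origin" not in df:
        df["origin"] = "reported"
    if "trip_code" not in df:
        df["trip_code"] = pd.NA
    if "is_fishing" not in df:
        df["is_fishing"] = pd.NA
    return df


def clean_pings(
    pings: pd.DataFrame, land_polygons: shapely.Geometry | None = None
) -> pd.DataFrame:
    """Drop exact (vessel, timestamp) duplicates and points on land.

    Order is preserved; removal counts are logged.
    """
    df = _ensure_columns(pings)
    n0 = len(df)
    df = df.drop_duplicates(subset=["vessel_id", "timestamp"], keep="first")
    n_dup = n0 - len(df)
    n_land = 0
    if land_polygons is not None and len(df):
        on_land = shapely.contains_xy(
            land_polygons, df["lon"].to_numpy(), df["lat"].to_numpy()
        )
        n_land = int(on_land.sum())
        df = df[~on_land]
    if n_dup or n_land:
        log.info("clean_pings removed %d duplicates and %d on-land points", n_dup, n_land)
    return df.reset_index(drop=True)


def assign_trip_codes(pings: pd.DataFrame, tz: str = "Europe/Madrid") -> pd.DataFrame:
    """Assign trip_code = ``<vessel>:<local date>``.

    Landings are daily, so vessel + local calendar date identifies a trip.
    """
    df = _ensure_columns(pings)
    if df.empty:
        return df
    ts = pd.to_datetime(df["timestamp"], utc=True)
    local_date = ts.dt.tz_convert(tz).dt.date.astype(str)
    df["trip_code"] = df["vessel_id"].astype(str) + ":" + local_date
    return df


def interpolate_track_10min(trip: pd.DataFrame) -> pd.DataFrame:
    """Densify one trip's pings to a 10-min mesh anchored at its first ping.

    Positions are interpolated linearly in (lat, lon) between bracketing
    reported pings; reported pings are kept verbatim.  The speed of every
    interpolated ping is recomputed as segment distance / segment duration
    over the resulting mesh, in knots.  A single ping is returned unchanged
    with a warning.
    """
    df = _ensure_columns(trip).sort_values("timestamp").reset_index(drop=True)
    if len(df) < 2:
        log.warning("trip with %d ping(s); nothing to interpolate", len(df))
        return df
    ts = pd.to_datetime(df["timestamp"], utc=True)
    t0 = ts.iloc[0]
    t_end = ts.iloc[-1]
    step = pd.Timedelta(minutes=PING_INTERVAL_MIN)
    mesh = pd.date_range(t0, t_end, freq=step)
    existing = set(ts)
    new_times = [t for t in mesh if t not in existing]

    t_sec = (ts - t0).dt.total_seconds().to_numpy()
    lat = df["lat"].to_numpy(dtype=float)
    lon = df["lon"].to_numpy(dtype=float)
    rows = []
    for t in new_times:
        s = (t - t0).total_seconds()
        rows.append(
            {
                "vessel_id": df["vessel_id"].iloc[0],
                "timestamp": t,
                "lat": float(np.interp(s, t_sec, lat)),
                "lon": float(np.interp(s, t_sec, lon)),
                "speed": np.nan,
                "course": np.nan,
                "origin": "interpolated",
                "trip_code": df["trip_code"].iloc[0],
                "is_fishing": pd.NA,
            }
        )
    if not rows:
        return df
    out = pd.concat([df, pd.DataFrame(rows, columns=df.columns)], ignore_index=True)
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True)
    out = out.sort_values("timestamp", ignore_index=True)

    # recompute interpolated speeds over the densified series
    interp = out["origin"].to_numpy() == "interpolated"
    if interp.any():
        la = out["lat"].to_numpy()
        lo = out["lon"].to_numpy()
        tt = out["timestamp"].astype("int64").to_numpy() / 1e9
        seg_km = np.array(
            [haversine_km(la[i - 1], lo[i - 1], la[i], lo[i]) for i in range(1, len(out))]
        )
        seg_h = np.diff(tt) / 3600.0
        with np.errstate(divide="ignore", invalid="ignore"):
            kn = np.where(seg_h > 0, seg_km / seg_h / KM_PER_NM, 0.0)
        speeds = out["speed"].to_numpy(dtype=float)
        idx = np.where(interp)[0]
        for i in idx:
            speeds[i] = kn[i - 1] if i > 0 else kn[0]
        out["speed"] = speeds
    return out


def classify_fishing(
    pings: pd.DataFrame,
    speed_range_kn: tuple[float, float] = DEFAULT_SPEED_RANGE_KN,
    depth_range_m: tuple[float, float] = DEFAULT_DEPTH_RANGE_M,
    bathymetry: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
) -> pd.DataFrame:
    """Mark pings as fishing when speed AND depth fall inside the filters.

    ``bathymetry(lat, lon)`` returns positive depths (m); pings where it
    returns NaN are marked not fishing and counted in the log.
    """
    if not speed_range_kn[0] < speed_range_kn[1]:
        raise ConfigError(f"speed range must be increasing, got {speed_range_kn}")
    if not depth_range_m[0] < depth_range_m[1]:
        raise ConfigError(f"depth range must be increasing, got {depth_range_m}")
    df = _ensure_columns(pings).copy()
    if df.empty:
        return df
    speed = df["speed"].to_numpy(dtype=float)
    ok_speed = (speed >= speed_range_kn[0]) & (speed <= speed_range_kn[1])
    if bathymetry is None:
        ok_depth = np.ones(len(df), dtype=bool)
    else:
        depth = np.asarray(
            bathymetry(df["lat"].to_numpy(dtype=float), df["lon"].to_numpy(dtype=float)),
            dtype=float,
        )
        missing = ~np.isfinite(depth)
        if missing.any():
            log.warning("%d pings lack bathymetry; marked not fishing", int(missing.sum()))
        ok_depth = (
            np.isfinite(depth)
            & (depth >= depth_range_m[0])
            & (depth <= depth_range_m[1])
        )
    df["is_fishing"] = ok_speed & ok_depth
    return df


def fishing_time(trip: pd.DataFrame) -> float:
    """Fishing hours of one trip: (fishing pings) x 10 min.

    Logs a warning when the daily legal limit (12 h) is exceeded; the value
    is reported, never truncated.
    """
    n = int(trip["is_fishing"].fillna(False).sum())
    hours = n * PING_INTERVAL_MIN / 60.0
    if hours > DAILY_FISHING_LIMIT_H:
        log.warning("trip %s: fishing time %.2f h exceeds the 12 h daily limit",
                    trip["trip_code"].iloc[0] if len(trip) else "?", hours)
    return hours


def allocate_landings(
    trip: pd.DataFrame, landings: pd.DataFrame
) -> tuple[pd.DataFrame, list[str]]:
    """Split each species' daily landed kg and € equally over the trip's
    fishing pings.

    Parameters
    ----------
    trip : classified pings of one trip.
    landings : rows with columns species_code, weight_kg, revenue_eur
        already filtered to this trip's (vessel, date).

    Returns
    -------
    (allocations, issues) where allocations has one row per
    (fishing ping, species): ping_index, species_code, weight_kg, revenue_eur.
    A trip with landings but no fishing pings yields no allocations and an
    issue string; those landings are excluded from the maps.
    """
    fishing_idx = trip.index[trip["is_fishing"].fillna(False).astype(bool)]
    issues: list[str] = []
    rows: list[dict] = []
    if landings.empty:
        return pd.DataFrame(
            columns=["ping_index", "species_code", "weight_kg", "revenue_eur"]
        ), issues
    if len(fishing_idx) == 0:
        trip_code = trip["trip_code"].iloc[0] if len(trip) else "?"
        issues.append(
            f"trip {trip_code}: {len(landings)} landing record(s) but no fishing "
            "pings; landings left unallocated"
        )
        return pd.DataFrame(
            columns=["ping_index", "species_code", "weight_kg", "revenue_eur"]
        ), issues
    n = len(fishing_idx)
    for rec in landings.itertuples(index=False):
        w = float(rec.weight_kg) / n
        r = float(rec.revenue_eur) / n
        for i in fishing_idx:
            rows.append(
                {"ping_index": int(i), "species_code": rec.species_code,
                 "weight_kg": w, "revenue_eur": r}
            )
    return pd.DataFrame(rows), issues


@dataclass(frozen=True)
class GridSpec:
    """Regular km grid in a local equirectangular projection.

    x = R cos(lat0) * lon_rad, y = R * lat_rad, centred on (lat0, lon0);
    adequate for maps spanning ~100 km.
    """

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    cell_size_km: float = 1.0

    def __post_init__(self) -> None:
        if not self.cell_size_km > 0:
            raise ConfigError("cell size must be positive")
        if not (self.lat_min < self.lat_max and self.lon_min < self.lon_max):
            raise ConfigError("bounding box must have positive extent")

    @property
    def lat0(self) -> float:
        return 0.5 * (self.lat_min + self.lat_max)

    def project(self, lat: np.ndarray, lon: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        k = EARTH_RADIUS_KM * math.cos(math.radians(self.lat0))
        x = k * np.radians(np.asarray(lon) - self.lon_min)
        y = EARTH_RADIUS_KM * np.radians(np.asarray(lat) - self.lat_min)
        return x, y

    def unproject(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        k = EARTH_RADIUS_KM * math.cos(math.radians(self.lat0))
        lon = self.lon_min + np.degrees(np.asarray(x) / k)
        lat = self.lat_min + np.degrees(np.asarray(y) / EARTH_RADIUS_KM)
        return lat, lon

    @property
    def shape(self) -> tuple[int, int]:
        x_max, y_max = self.project(np.array([self.lat_max]), np.array([self.lon_max]))
        nx = max(1, int(math.ceil(x_max[0] / self.cell_size_km)))
        ny = max(1, int(math.ceil(y_max[0] / self.cell_size_km)))
        return ny, nx


@dataclass
class EffortGrid:
    """Rasterized fleet activity: effort (h/km²), landings (kg/km²) and
    revenue per unit effort (€/(h·km²), NaN where no effort)."""

    spec: GridSpec
    effort: np.ndarray
    landings: np.ndarray
    revenue: np.ndarray

    @property
    def cell_area_km2(self) -> float:
        return self.spec.cell_size_km ** 2

    @property
    def rpue(self) -> np.ndarray:
        hours = self.effort * self.cell_area_km2
        with np.errstate(divide="ignore", invalid="ignore"):
            out = self.revenue / (hours * self.cell_area_km2)
        out[hours <= 0] = np.nan
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long CSV-ready table: cell_x, cell_y, layer, value."""
        ny, nx = self.effort.shape
        layers = {"effort_h_per_km2": self.effort,
                  "landings_kg_per_km2": self.landings,
                  "rpue_eur_per_h_km2": self.rpue}
        rows = []
        for name, arr in layers.items():
            ys, xs = np.nonzero(np.nan_to_num(arr) != 0)
            for y, x in zip(ys, xs):
                rows.append({"cell_x": int(x), "cell_y": int(y),
                             "layer": name, "value": float(arr[y, x])})
        return pd.DataFrame(rows, columns=["cell_x", "cell_y", "layer", "value"])

    def to_geojson(self) -> dict:
        """FeatureCollection of non-empty cell polygons with layer properties."""
        ny, nx = self.effort.shape
        cs = self.spec.cell_size_km
        features = []
        rpue = self.rpue
        for y in range(ny):
            for x in range(nx):
                if self.effort[y, x] == 0 and self.landings[y, x] == 0:
                    continue
                xs = np.array([x * cs, (x + 1) * cs, (x + 1) * cs, x * cs, x * cs])
                ys = np.array([y * cs, y * cs, (y + 1) * cs, (y + 1) * cs, y * cs])
                lat, lon = self.spec.unproject(xs, ys)
                features.append(
                    {
                        "type": "Feature",
                        "geometry": {
                            "type": "Polygon",
                            "coordinates": [[[float(lo), float(la)]
                                             for lo, la in zip(lon, lat)]],
                        },
                        "properties": {
                            "cell_x": x,
                            "cell_y": y,
                            "effort_h_per_km2": float(self.effort[y, x]),
                            "landings_kg_per_km2": float(self.landings[y, x]),
                            "rpue_eur_per_h_km2": None if np.isnan(rpue[y, x])
                            else float(rpue[y, x]),
                        },
                    }
                )
        return {"type": "FeatureCollection", "features": features}


def rasterize_effort(
    pings: pd.DataFrame,
    allocations: pd.DataFrame,
    spec: GridSpec,
    clip: bool = True,
) -> EffortGrid:
    """Accumulate fishing pings and their allocated landings onto the grid.

    Each fishing ping contributes 10 min of effort to its cell; layers are
    divided by cell area so units are per km².  Pings outside the box are
    dropped and counted when ``clip`` is true.
    """
    ny, nx = spec.shape
    effort_h = np.zeros((ny, nx))
    kg = np.zeros((ny, nx))
    eur = np.zeros((ny, nx))

    fishing = pings[pings["is_fishing"].fillna(False).astype(bool)]
    if len(fishing):
        x, y = spec.project(fishing["lat"].to_numpy(), fishing["lon"].to_numpy())
        ix = np.floor(x / spec.cell_size_km).astype(int)
        iy = np.floor(y / spec.cell_size_km).astype(int)
        inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        n_out = int((~inside).sum())
        if n_out:
            if not clip:
                raise InvalidInputError(
                    f"{n_out} fishing pings outside the grid bounding box"
                )
            log.info("rasterize_effort clipped %d pings outside the box", n_out)
        cell_of_ping = dict(
            zip(fishing.index[inside], zip(iy[inside], ix[inside]))
        )
        for cy, cx in cell_of_ping.values():
            effort_h[cy, cx] += PING_INTERVAL_MIN / 60.0
        if len(allocations):
            for rec in allocations.itertuples(index=False):
                cell = cell_of_ping.get(rec.ping_index)
                if cell is None:
                    continue
                kg[cell] += rec.weight_kg
                eur[cell] += rec.revenue_eur

    area = spec.cell_size_km ** 2
    return EffortGrid(spec=spec, effort=effort_h / area, landings=kg / area,
                      revenue=eur)


def process_fleet(
    pings: pd.DataFrame,
    landings: pd.DataFrame,
    bathymetry: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
    land_polygons: shapely.Geometry | None = None,
    speed_range_kn: tuple[float, float] = DEFAULT_SPEED_RANGE_KN,
    depth_range_m: tuple[float, float] = DEFAULT_DEPTH_RANGE_M,
    tz: str = "Europe/Madrid",
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Full ping pipeline: clean, code trips, interpolate, classify, allocate.

    ``landings`` needs columns date, vessel_id, species_code, weight_kg,
    revenue_eur.  Returns (classified pings, allocations, issues); allocation
    ``ping_index`` refers to the returned ping frame's index.
    """
    df = clean_pings(pings, land_polygons)
    df = assign_trip_codes(df, tz=tz)
    trips = []
    for _, trip in df.groupby("trip_code", sort=True):
        trips.append(interpolate_track_10min(trip))
    if trips:
        df = pd.concat(trips, ignore_index=True)
        df = df.sort_values(["vessel_id", "timestamp"], ignore_index=True)
    df = classify_fishing(df, speed_range_kn, depth_range_m, bathymetry)

    land = landings.copy()
    land["trip_code"] = (
        land["vessel_id"].astype(str) + ":" + land["date"].astype(str)
    )
    allocs = []
    issues: list[str] = []
    for code, trip in df.groupby("trip_code", sort=True):
        fishing_time(trip)  # logs over-limit trips
        trip_land = land[land["trip_code"] == code]
        alloc, trip_issues = allocate_landings(trip, trip_land)
        allocs.append(alloc)
        issues.extend(trip_issues)
    unmatched = set(land["trip_code"]) - set(df["trip_code"].dropna())
    for code in sorted(unmatched):
        issues.append(f"trip {code}: landings with no VMS pings; left unallocated")
    allocations = (
        pd.concat(allocs, ignore_index=True)
        if allocs
        else pd.DataFrame(columns=["ping_index", "species_code", "weight_kg", "revenue_eur"])
    )
    return df, allocations, issues
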
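"""Seeded synthetic survey and fleet generator.

Emulates the structure of a coastal bottom-trawl monitoring programme: each
survey day a vessel performs one haul in each of three depth strata; a GPS
logs the tow at 1-min cadence and observers note positions every 15 min; the
catch is sorted into landed / discarded fractions, subsampled, measured, and
a laboratory subsample is weighed.  The commercial fleet reports VMS pings
at 2-h cadence and lands daily, with per-species prices.

The geography is a synthetic shelf: a straight east-west coastline with the
sea to the south and depth increasing linearly offshore, so a closed-form
bathymetry and land polygon are available to every downstream stage.  All
randomness flows from one master seed through per-entity
``numpy.random.SeedSequence`` streams, so adding vessels or days does not
perturb existing draws.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from datetime import date as date_type, datetime, time, timedelta, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import shapely

from .errors import ConfigError
from .geometry import GeoPoint, GeoTrack, cut_haul_track, parse_gpx
from .species import Category, Individual, Sample, SpeciesRecord, SpeciesRegistry, TaxonGroup
from .survey import Haul, SurveyDataset, season_of

__all__ = [
    "COAST_LAT",
    "SpeciesSim",
    "StratumSim",
    "SimulationConfig",
    "synthetic_bathymetry",
    "land_polygon",
    "simulate_haul",
    "simulate_fleet_day",
    "generate_survey",
    "SurveyBundle",
]

KM_PER_NM = 1.852
KM_PER_DEG = math.pi * 6371.0 / 180.0

#: Latitude of the synthetic east-west coastline; land lies to the north.
COAST_LAT = 41.0

#: Seabed slope of the synthetic shelf (m of depth per km offshore).
SHELF_SLOPE_M_PER_KM = 15.0


def synthetic_bathymetry(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Depth (m, positive down) of the synthetic shelf at given positions."""
    lat = np.asarray(lat, dtype=float)
    offshore_km = (COAST_LAT - lat) * KM_PER_DEG
    return np.maximum(0.0, offshore_km * SHELF_SLOPE_M_PER_KM)


def land_polygon() -> shapely.Geometry:
    """Rectangle covering the synthetic landmass north of the coastline."""
    return shapely.box(-5.0, COAST_LAT, 10.0, 45.0)


def _lat_at_depth(depth_m: float) -> float:
    return COAST_LAT - depth_m / SHELF_SLOPE_M_PER_KM / KM_PER_DEG


@dataclass(frozen=True)
class SpeciesSim:
    """Truth parameters for one simulated taxon."""

    record: SpeciesRecord
    log_length_mean: float  # lognormal parameters of the length distribution
    log_length_sd: float
    density_per_km2: dict[str, float]  # per-stratum true density (indiv/km²)
    discard_rate: float = 0.1  # fraction of individuals discarded
    price_eur_per_kg: float = 5.0
    weight_noise_sd: float = 0.05  # lognormal sd around W = a L^b


@dataclass(frozen=True)
class StratumSim:
    name: str
    depth_m: float


def _default_species() -> list[SpeciesSim]:
    # Parameters in the range reported for NW Mediterranean demersal taxa.
    return [
        SpeciesSim(
            record=SpeciesRecord("HKE", "Merluccius merluccius", a=0.0051, b=3.02,
                                 length_min=4.0, length_max=90.0, mcrs=20.0,
                                 group=TaxonGroup.FISH),
            log_length_mean=math.log(18.0), log_length_sd=0.35,
            density_per_km2={"shallow": 150.0, "mid": 260.0, "deep": 60.0},
            discard_rate=0.15, price_eur_per_kg=6.5,
        ),
        SpeciesSim(
            record=SpeciesRecord("MUT", "Mullus barbatus", a=0.0086, b=3.04,
                                 length_min=5.0, length_max=30.0, mcrs=11.0,
                                 group=TaxonGroup.FISH),
            log_length_mean=math.log(13.0), log_length_sd=0.25,
            density_per_km2={"shallow": 420.0, "mid": 90.0, "deep": 0.0},
            discard_rate=0.1, price_eur_per_kg=8.0,
        ),
        SpeciesSim(
            record=SpeciesRecord("DPS", "Parapenaeus longirostris", a=0.0022, b=2.64,
                                 length_min=0.8, length_max=4.5, mcrs=2.0,
                                 group=TaxonGroup.CRUSTACEAN),
            log_length_mean=math.log(2.4), log_length_sd=0.22,
            density_per_km2={"shallow": 0.0, "mid": 900.0, "deep": 250.0},
            discard_rate=0.05, price_eur_per_kg=14.0,
        ),
        SpeciesSim(
            record=SpeciesRecord("ARA", "Aristeus antennatus", a=0.0017, b=2.90,
                                 length_min=1.0, length_max=7.5, mcrs=None,
                                 group=TaxonGroup.CRUSTACEAN),
            log_length_mean=math.log(3.6), log_length_sd=0.22,
            density_per_km2={"shallow": 0.0, "mid": 40.0, "deep": 700.0},
            discard_rate=0.02, price_eur_per_kg=30.0,
        ),
        SpeciesSim(
            record=SpeciesRecord("OCC", "Octopus vulgaris", a=0.55, b=2.35,
                                 length_min=4.0, length_max=28.0, mcrs=None,
                                 group=TaxonGroup.CEPHALOPOD),
            log_length_mean=math.log(11.0), log_length_sd=0.25,
            density_per_km2={"shallow": 70.0, "mid": 25.0, "deep": 0.0},
            discard_rate=0.05, price_eur_per_kg=9.0,
        ),
    ]


#: Nine ports on the synthetic coast, three per area (north / central / south).
DEFAULT_PORTS: dict[str, tuple[str, float]] = {
    # port -> (area, longitude on the coastline)
    "Roses": ("north", 3.2),
    "Palamos": ("north", 3.1),
    "Blanes": ("north", 2.8),
    "Arenys": ("central", 2.55),
    "Barcelona": ("central", 2.2),
    "Vilanova": ("central", 1.7),
    "Tarragona": ("south", 1.25),
    "Cambrils": ("south", 1.07),
    "SantCarles": ("south", 0.86),
}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic survey; the seed fixes the entire output."""

    seed: int = 0
    n_vessels: int = 1
    n_days: int = 4
    hauls_per_trip: int = 3  # one per depth stratum
    start_date: date_type = date_type(2021, 3, 1)
    species: list[SpeciesSim] = field(default_factory=_default_species)
    strata: list[StratumSim] = field(
        default_factory=lambda: [
            StratumSim("shallow", 90.0),
            StratumSim("mid", 350.0),
            StratumSim("deep", 620.0),
        ]
    )
    gear_width_m: float = 25.0
    tow_speed_kn: float = 3.0
    tow_duration_min: int = 60
    gps_cadence_min: int = 1
    onboard_cadence_min: int = 15
    vms_cadence_h: float = 2.0
    heading_noise_deg: float = 4.0
    max_measured_per_sample: int = 120  # larger catches are subsampled
    lab_fraction: float = 0.3  # share of measured individuals weighed in the lab
    ports: dict[str, tuple[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_PORTS)
    )

    def stratum(self, name: str) -> StratumSim:
        for s in self.strata:
            if s.name == name:
                return s
        raise ConfigError(f"unknown stratum {name!r}")

    def registry(self) -> SpeciesRegistry:
        return SpeciesRegistry(sp.record for sp in self.species)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def _gpx_text(points: list[GeoPoint]) -> str:
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        '<gpx version="1.1" creator="trawlkit-sim" '
        'xmlns="http://www.topografix.com/GPX/1/1">',
        "<trk><trkseg>",
    ]
    for p in points:
        t = p.timestamp.astimezone(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")
        lines.append(f'<trkpt lat="{p.lat:.6f}" lon="{p.lon:.6f}"><time>{t}</time></trkpt>')
    lines.append("</trkseg></trk></gpx>")
    return "\n".join(lines)


@dataclass
class HaulBundle:
    haul: Haul
    samples: list[Sample]
    individuals: list[Individual]
    gpx_text: str
    onboard_positions: list[GeoPoint]
    truth: dict


def simulate_haul(
    config: SimulationConfig,
    stratum_name: str,
    haul_id: str,
    vessel_id: str,
    port: str,
    day: date_type,
    start: datetime,
    rng: np.random.Generator,
) -> HaulBundle:
    """Simulate one tow: track, onboard fixes, sorted samples, individuals.

    The tow runs along-shore at the stratum's isobath at the configured speed
    with heading noise; the catch per species is Poisson in (true density x
    swept area), split into landed / discarded by the species' discard rate.
    """
    stratum = config.stratum(stratum_name)
    area, port_lon = config.ports[port]

    # --- track -------------------------------------------------------------
    lat0 = _lat_at_depth(stratum.depth_m)
    lon0 = port_lon + rng.uniform(-0.05, 0.05)
    speed_kmh = config.tow_speed_kn * KM_PER_NM
    step_km = speed_kmh * config.gps_cadence_min / 60.0
    heading = rng.uniform(0, 360)  # tow direction; kept near-constant
    n_pts = config.tow_duration_min // config.gps_cadence_min + 1
    lat, lon = lat0, lon0
    points: list[GeoPoint] = []
    for i in range(n_pts):
        points.append(
            GeoPoint(lat=lat, lon=lon,
                     timestamp=start + timedelta(minutes=i * config.gps_cadence_min))
        )
        heading += rng.normal(0.0, config.heading_noise_deg)
        dlat = step_km * math.cos(math.radians(heading)) / KM_PER_DEG
        dlon = (step_km * math.sin(math.radians(heading))
                / (KM_PER_DEG * math.cos(math.radians(lat))))
        lat, lon = lat + dlat, lon + dlon

    onboard = [
        p for i, p in enumerate(points)
        if i % config.onboard_cadence_min == 0 or i == n_pts - 1
    ]
    gpx = _gpx_text(points)
    track = cut_haul_track(parse_gpx(gpx), onboard)
    haul = Haul.from_track(
        haul_id=haul_id, vessel_id=vessel_id, date=day, port=port, area=area,
        depth_stratum_m=stratum.depth_m, gear_width_m=config.gear_width_m,
        track=track, onboard_positions=onboard,
    )

    # --- catch -------------------------------------------------------------
    samples: list[Sample] = []
    individuals: list[Individual] = []
    truth_catch_kg: dict[str, float] = {}
    pools: dict[Category, list[tuple[str, float, float]]] = {
        Category.LANDED: [], Category.DISCARDED: [],
    }
    for sp in config.species:
        density = sp.density_per_km2.get(stratum_name, 0.0)
        n = int(rng.poisson(density * haul.swept_area_km2))
        if n == 0:
            continue
        lengths = np.exp(rng.normal(sp.log_length_mean, sp.log_length_sd, size=n))
        lengths = np.clip(lengths, sp.record.length_min, sp.record.length_max)
        weights_g = (
            sp.record.a * lengths ** sp.record.b
            * np.exp(rng.normal(0.0, sp.weight_noise_sd, size=n))
        )
        discard = rng.random(n) < sp.discard_rate
        for L, w, d in zip(lengths, weights_g, discard):
            cat = Category.DISCARDED if d else Category.LANDED
            pools[cat].append((sp.record.code, float(L), float(w)))
        truth_catch_kg[sp.record.code] = truth_catch_kg.get(sp.record.code, 0.0) \
            + float(weights_g[~discard].sum() / 1000.0)

    for cat, pool in pools.items():
        if not pool:
            continue
        sample_id = f"{haul_id}-{cat.value}"
        fraction_w_kg = sum(w for _, _, w in pool) / 1000.0
        n_total = len(pool)
        if n_total > config.max_measured_per_sample:
            idx = rng.choice(n_total, size=config.max_measured_per_sample, replace=False)
            measured = [pool[i] for i in sorted(idx)]
        else:
            measured = pool
        sub_w_kg = sum(w for _, _, w in measured) / 1000.0
        samples.append(
            Sample(sample_id=sample_id, haul_id=haul_id, category=cat,
                   subsample_weight=sub_w_kg, fraction_weight=fraction_w_kg)
        )
        n_lab = int(round(config.lab_fraction * len(measured)))
        lab_idx = set(rng.choice(len(measured), size=n_lab, replace=False).tolist())
        for i, (code, L, w) in enumerate(measured):
            if i in lab_idx:
                individuals.append(Individual(species_code=code, length=L,
                                              sample_id=sample_id, weight=w,
                                              measured_in="laboratory"))
            else:
                individuals.append(Individual(species_code=code, length=L,
                                              sample_id=sample_id,
                                              measured_in="field"))

    truth = {
        "stratum": stratum_name,
        "true_density_per_km2": {
            sp.record.code: sp.density_per_km2.get(stratum_name, 0.0)
            for sp in config.species
        },
        "landed_catch_kg": truth_catch_kg,
        "n_caught": {cat.value: len(pool) for cat, pool in pools.items()},
    }
    return HaulBundle(haul=haul, samples=samples, individuals=individuals,
                      gpx_text=gpx, onboard_positions=onboard, truth=truth)


def simulate_lab_pairs(
    sp: SpeciesSim, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` laboratory (length cm, weight g) pairs for one species:
    lognormal lengths, allometric weights with lognormal measurement noise."""
    lengths = np.exp(rng.normal(sp.log_length_mean, sp.log_length_sd, size=n))
    lengths = np.clip(lengths, sp.record.length_min, sp.record.length_max)
    weights = (
        sp.record.a * lengths ** sp.record.b
        * np.exp(rng.normal(0.0, sp.weight_noise_sd, size=n))
    )
    return np.column_stack([lengths, weights])


def simulate_fleet_day(
    config: SimulationConfig, day: date_type, vessel_id: str,
    rng: np.random.Generator, port: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One commercial vessel-day: VMS pings at 2-h cadence plus landings.

    The vessel steams offshore at high speed, trawls inside the legal depth
    band at trawling speed, and steams home.  Truth activity labels are kept
    in the ``truth_fishing`` column; landings equal the simulated catch.
    """
    if port is None:
        port = list(config.ports)[rng.integers(len(config.ports))]
    _, port_lon = config.ports[port]
    cadence = timedelta(hours=config.vms_cadence_h)
    t = datetime.combine(day, time(4, 0), tzinfo=timezone.utc)

    # leg plan: 1 steaming ping out, 4 fishing pings towing along-shore,
    # 1 steaming ping home
    rows = []
    fish_depth = rng.uniform(120.0, 850.0)
    fish_lat = _lat_at_depth(fish_depth)
    lon = port_lon + rng.uniform(-0.1, 0.1)
    legs = (
        [("steam", rng.uniform(7.5, 10.5))]
        + [("fish", float(np.clip(rng.normal(config.tow_speed_kn, 0.3), 1.5, 4.2)))] * 4
        + [("steam", rng.uniform(7.5, 10.5))]
    )
    for i, (kind, speed) in enumerate(legs):
        if kind == "steam":
            lat = _lat_at_depth(rng.uniform(5.0, 30.0))
        else:
            lat = fish_lat + rng.normal(0.0, 0.002)
            lat = min(lat, _lat_at_depth(60.0))  # stay inside the legal band
            lat = max(lat, _lat_at_depth(950.0))
            # the tow advances along-shore at trawling speed
            lon += (speed * KM_PER_NM * config.vms_cadence_h
                    / (KM_PER_DEG * math.cos(math.radians(lat))))
        rows.append(
            {"vessel_id": vessel_id, "timestamp": t + i * cadence,
             "lat": lat, "lon": lon, "speed": speed,
             "course": float(rng.uniform(0, 360)),
             "truth_fishing": kind == "fish"}
        )
    pings = pd.DataFrame(rows)

    landings_rows = []
    for sp in config.species:
        mean_kg = sum(sp.density_per_km2.values()) / max(len(sp.density_per_km2), 1)
        kg = float(rng.gamma(shape=4.0, scale=mean_kg / 50.0 + 0.5))
        landings_rows.append(
            {"date": day.isoformat(), "vessel_id": vessel_id, "port": port,
             "species_code": sp.record.code, "weight_kg": round(kg, 2),
             "revenue_eur": round(kg * sp.price_eur_per_kg, 2)}
        )
    return pings, pd.DataFrame(landings_rows)


@dataclass
class SurveyBundle:
    """Everything one simulated campaign produced, plus the truth book."""

    dataset: SurveyDataset
    gpx_by_haul: dict[str, str]
    vms_pings: pd.DataFrame
    landings: pd.DataFrame
    truth: dict


def generate_survey(config: SimulationConfig, out_dir: str | Path | None = None) -> SurveyBundle:
    """Generate a full consistent dataset: hauls, samples, individuals, GPX
    texts, VMS pings and landings; optionally write it to ``out_dir``.

    Hauls number n_vessels x n_days x hauls_per_trip; vessels rotate through
    the configured ports.
    """
    registry = config.registry()
    dataset = SurveyDataset(registry=registry)
    gpx_by_haul: dict[str, str] = {}
    truth: dict = {"config_seed": config.seed, "hauls": {}}
    port_names = list(config.ports)

    vms_frames, landing_frames = [], []
    for v in range(config.n_vessels):
        vessel_id = f"SV{v + 1:02d}"
        for d in range(config.n_days):
            day = config.start_date + timedelta(days=d)
            port = port_names[(v * config.n_days + d) % len(port_names)]
            for s in range(config.hauls_per_trip):
                stratum = config.strata[s % len(config.strata)]
                haul_id = f"H{v + 1:02d}{d + 1:03d}{s + 1}"
                start = datetime.combine(day, time(6, 0), tzinfo=timezone.utc) \
                    + timedelta(hours=3 * s)
                bundle = simulate_haul(
                    config, stratum.name, haul_id, vessel_id, port, day, start,
                    _rng(config.seed, 1, v, d, s),
                )
                dataset.add_haul(bundle.haul)
                for sample in bundle.samples:
                    dataset.add_sample(sample)
                dataset.add_individuals(bundle.individuals)
                gpx_by_haul[haul_id] = bundle.gpx_text
                truth["hauls"][haul_id] = bundle.truth
            fleet_pings, fleet_landings = simulate_fleet_day(
                config, day, f"FV{v + 1:02d}", _rng(config.seed, 2, v, d), port=port,
            )
            vms_frames.append(fleet_pings)
            landing_frames.append(fleet_landings)

    vms = pd.concat(vms_frames, ignore_index=True) if vms_frames else pd.DataFrame()
    landings = (
        pd.concat(landing_frames, ignore_index=True) if landing_frames else pd.DataFrame()
    )
    bundle = SurveyBundle(dataset=dataset, gpx_by_haul=gpx_by_haul,
                          vms_pings=vms, landings=landings, truth=truth)
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(bundle: SurveyBundle, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "gpx").mkdir(exist_ok=True)
    files: list[str] = []
    for haul_id, text in bundle.gpx_by_haul.items():
        p = out_dir / "gpx" / f"{haul_id}.gpx"
        p.write_text(text)
        files.append(str(p.relative_to(out_dir)))
    ds = bundle.dataset
    for name, df in [
        ("hauls.csv", ds.hauls_table()),
        ("samples.csv", ds.samples_table()),
        ("individuals.csv", ds.individuals_table()),
        ("vms.csv", bundle.vms_pings),
        ("landings.csv", bundle.landings),
    ]:
        df.to_csv(out_dir / name, index=False)
        files.append(name)
    ds.registry.to_csv(out_dir / "species.csv")
    files.append("species.csv")
    manifest = {"files": sorted(files), "truth": bundle.truth}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
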
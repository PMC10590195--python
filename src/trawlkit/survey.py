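"""Haul records and the in-memory survey dataset bundle.

A haul is one trawl tow — the sampling unit of the survey.  The dataset
bundle groups hauls, their sorted samples, the measured individuals and the
species registry so downstream stages (QC, standardization, products) share
one container.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as date_type
from typing import Iterable, Sequence

import pandas as pd

from .errors import InconsistencyError, InvalidInputError, UnknownEntityError
from .geometry import GeoPoint, GeoTrack, swept_area, swept_distance
from .species import Individual, Sample, SpeciesRegistry

__all__ = ["AREAS", "SEASONS", "Haul", "SurveyDataset", "season_of"]

AREAS = ("north", "central", "south")
SEASONS = ("spring", "summer", "autumn", "winter")

_AREA_TOL = 1e-9


def season_of(d: date_type) -> str:
    """Meteorological season of a date (Mar-May spring, Jun-Aug summer, ...)."""
    return SEASONS[(d.month % 12) // 3 - 1] if d.month >= 3 else SEASONS[3]


@dataclass
class Haul:
    """One trawl tow with its cut track and swept-area geometry.

    ``swept_distance_km`` and ``swept_area_km2`` must be mutually consistent
    with the gear width: area = distance x width / 1000.
    """

    haul_id: str
    vessel_id: str
    date: date_type
    port: str
    area: str
    season: str
    depth_stratum_m: float
    gear_width_m: float
    swept_distance_km: float
    swept_area_km2: float
    track: GeoTrack | None = None
    onboard_positions: tuple[GeoPoint, ...] = ()

    def __post_init__(self) -> None:
        if not self.gear_width_m > 0:
            raise InvalidInputError(f"haul {self.haul_id}: gear width must be positive")
        if self.swept_distance_km < 0:
            raise InvalidInputError(f"haul {self.haul_id}: swept distance must be >= 0")
        if self.area not in AREAS:
            raise InvalidInputError(f"haul {self.haul_id}: unknown area {self.area!r}")
        if self.season not in SEASONS:
            raise InvalidInputError(f"haul {self.haul_id}: unknown season {self.season!r}")
        expected = self.swept_distance_km * self.gear_width_m / 1000.0
        if abs(self.swept_area_km2 - expected) > _AREA_TOL:
            raise InconsistencyError(
                f"haul {self.haul_id}: swept_area {self.swept_area_km2} != "
                f"SD*GW = {expected}"
            )

    @classmethod
    def from_track(
        cls,
        haul_id: str,
        vessel_id: str,
        date: date_type,
        port: str,
        area: str,
        depth_stratum_m: float,
        gear_width_m: float,
        track: GeoTrack,
        onboard_positions: Sequence[GeoPoint] = (),
        season: str | None = None,
    ) -> "Haul":
        sd = swept_distance(track)
        return cls(
            haul_id=haul_id,
            vessel_id=vessel_id,
            date=date,
            port=port,
            area=area,
            season=season or season_of(date),
            depth_stratum_m=depth_stratum_m,
            gear_width_m=gear_width_m,
            swept_distance_km=sd,
            swept_area_km2=swept_area(sd, gear_width_m),
            track=track,
            onboard_positions=tuple(onboard_positions),
        )

    @property
    def year(self) -> int:
        return self.date.year


@dataclass
class SurveyDataset:
    """All survey tables of a monitoring campaign, cross-referenced by id."""

    registry: SpeciesRegistry
    hauls: dict[str, Haul] = field(default_factory=dict)
    samples: dict[str, Sample] = field(default_factory=dict)
    individuals: list[Individual] = field(default_factory=list)

    def add_haul(self, haul: Haul) -> None:
        if haul.haul_id in self.hauls:
            raise InconsistencyError(f"duplicate haul id {haul.haul_id!r}")
        self.hauls[haul.haul_id] = haul

    def add_sample(self, sample: Sample) -> None:
        if sample.sample_id in self.samples:
            raise InconsistencyError(f"duplicate sample id {sample.sample_id!r}")
        self.samples[sample.sample_id] = sample

    def add_individuals(self, individuals: Iterable[Individual]) -> None:
        self.individuals.extend(individuals)

    def haul_of_sample(self, sample_id: str) -> Haul:
        sample = self.samples.get(sample_id)
        if sample is None:
            raise UnknownEntityError(f"sample {sample_id!r} not in dataset")
        haul = self.hauls.get(sample.haul_id)
        if haul is None:
            raise UnknownEntityError(
                f"sample {sample_id!r} references missing haul {sample.haul_id!r}"
            )
        return haul

    def individuals_by_sample(self) -> dict[str, list[Individual]]:
        out: dict[str, list[Individual]] = {}
        for ind in self.individuals:
            out.setdefault(ind.sample_id, []).append(ind)
        return out

    def hauls_table(self) -> pd.DataFrame:
        rows = [
            {
                "haul_id": h.haul_id,
                "vessel_id": h.vessel_id,
                "date": h.date,
                "port": h.port,
                "area": h.area,
                "season": h.season,
                "year": h.year,
                "depth_stratum_m": h.depth_stratum_m,
                "gear_width_m": h.gear_width_m,
                "swept_distance_km": h.swept_distance_km,
                "swept_area_km2": h.swept_area_km2,
            }
            for h in self.hauls.values()
        ]
        return pd.DataFrame(rows)

    def samples_table(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": s.sample_id,
                "haul_id": s.haul_id,
                "category": s.category.value,
                "subsample_weight_kg": s.subsample_weight,
                "fraction_weight_kg": s.fraction_weight,
                "sp": s.sp,
                "dp": s.dp,
            }
            for s in self.samples.values()
        ]
        return pd.DataFrame(rows)

    def individuals_table(self) -> pd.DataFrame:
        rows = [
            {
                "species_code": i.species_code,
                "length_cm": i.length,
                "weight_g": i.weight,
                "sample_id": i.sample_id,
                "measured_in": i.measured_in,
            }
            for i in self.individuals
        ]
        return pd.DataFrame(rows)
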
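"""Load a survey dataset from the on-disk CSV + GPX layout the simulator
(and the field programme) emits."""

from __future__ import annotations

from datetime import date
from pathlib import Path

import pandas as pd

from .errors import InvalidInputError
from .geometry import GeoTrack, cut_haul_track, parse_gpx
from .species import Category, Individual, Sample, SpeciesRegistry
from .survey import Haul, SurveyDataset

__all__ = ["load_survey"]


def load_survey(directory: str | Path) -> SurveyDataset:
    """Read species.csv, hauls.csv, samples.csv, individuals.csv and gpx/
    from ``directory`` into a :class:`SurveyDataset`.

    Tracks are re-cut from the GPX files using the haul's recorded time
    window, so swept distance/area are recomputed, not trusted from the CSV.
    """
    d = Path(directory)
    for required in ("species.csv", "hauls.csv", "samples.csv", "individuals.csv"):
        if not (d / required).exists():
            raise InvalidInputError(f"missing {required} in {d}")

    registry = SpeciesRegistry.from_csv(d / "species.csv")
    dataset = SurveyDataset(registry=registry)

    hauls = pd.read_csv(d / "hauls.csv")
    for row in hauls.itertuples(index=False):
        gpx_path = d / "gpx" / f"{row.haul_id}.gpx"
        track: GeoTrack | None = None
        if gpx_path.exists():
            track = parse_gpx(gpx_path.read_text())
        if track is not None:
            haul = Haul.from_track(
                haul_id=str(row.haul_id), vessel_id=str(row.vessel_id),
                date=date.fromisoformat(str(row.date)), port=str(row.port),
                area=str(row.area), depth_stratum_m=float(row.depth_stratum_m),
                gear_width_m=float(row.gear_width_m), track=track,
                onboard_positions=(track.points[0], track.points[-1]),
                season=str(row.season),
            )
        else:
            haul = Haul(
                haul_id=str(row.haul_id), vessel_id=str(row.vessel_id),
                date=date.fromisoformat(str(row.date)), port=str(row.port),
                area=str(row.area), season=str(row.season),
                depth_stratum_m=float(row.depth_stratum_m),
                gear_width_m=float(row.gear_width_m),
                swept_distance_km=float(row.swept_distance_km),
                swept_area_km2=float(row.swept_area_km2),
            )
        dataset.add_haul(haul)

    samples = pd.read_csv(d / "samples.csv")
    for row in samples.itertuples(index=False):
        dataset.add_sample(
            Sample(
                sample_id=str(row.sample_id), haul_id=str(row.haul_id),
                category=Category(row.category),
                subsample_weight=float(row.subsample_weight_kg),
                fraction_weight=float(row.fraction_weight_kg),
                sp=float(row.sp) if not pd.isna(row.sp) else None,
                dp=float(row.dp),
            )
        )

    individuals = pd.read_csv(d / "individuals.csv")
    dataset.add_individuals(
        Individual(
            species_code=str(row.species_code), length=float(row.length_cm),
            weight=None if pd.isna(row.weight_g) else float(row.weight_g),
            sample_id=str(row.sample_id), measured_in=str(row.measured_in),
        )
        for row in individuals.itertuples(index=False)
    )
    return dataset
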
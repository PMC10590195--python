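from __future__ import annotations

from datetime import date

import numpy as np
import pytest

from trawlkit.simulate import SimulationConfig, generate_survey
from trawlkit.species import (
    Category,
    Individual,
    Sample,
    SpeciesRecord,
    SpeciesRegistry,
    TaxonGroup,
)
from trawlkit.survey import Haul, SurveyDataset


@pytest.fixture(scope="session")
def registry() -> SpeciesRegistry:
    return SpeciesRegistry(
        [
            SpeciesRecord("HKE", "Merluccius merluccius", a=0.0051, b=3.02,
                          length_min=5.0, length_max=90.0, mcrs=20.0,
                          group=TaxonGroup.FISH),
            SpeciesRecord("DPS", "Parapenaeus longirostris", a=0.0022, b=2.64,
                          length_min=0.8, length_max=4.5, mcrs=2.0,
                          group=TaxonGroup.CRUSTACEAN),
            SpeciesRecord("TOY", "Toyus exactus", a=0.01, b=3.0,
                          length_min=1.0, length_max=50.0, mcrs=None,
                          group=TaxonGroup.FISH),
        ]
    )


@pytest.fixture(scope="session")
def survey_bundle():
    """Small deterministic synthetic campaign shared by read-only tests."""
    return generate_survey(SimulationConfig(seed=7, n_vessels=1, n_days=3))


def make_random_dataset(
    registry: SpeciesRegistry,
    rng: np.random.Generator,
    n_hauls: int = 10,
    n_species: int = 3,
) -> SurveyDataset:
    """Randomized hand-built dataset (no tracks) for oracle comparisons."""
    dataset = SurveyDataset(registry=registry)
    ports = [("Roses", "north"), ("Barcelona", "central"), ("Tarragona", "south")]
    codes = [r.code for r in registry][:n_species]
    for h in range(n_hauls):
        port, area = ports[h % len(ports)]
        sd = float(rng.uniform(1.0, 6.0))
        gw = float(rng.uniform(20.0, 60.0))
        haul = Haul(
            haul_id=f"R{h:03d}", vessel_id="SV01",
            date=date(2021, 1 + (h % 12), 1 + h % 28), port=port, area=area,
            season=("winter", "spring", "summer", "autumn")[h % 4],
            depth_stratum_m=float(rng.uniform(80, 700)), gear_width_m=gw,
            swept_distance_km=sd, swept_area_km2=sd * gw / 1000.0,
        )
        dataset.add_haul(haul)
        for cat in (Category.LANDED, Category.DISCARDED):
            sid = f"R{h:03d}-{cat.value}"
            sub = float(rng.uniform(1.0, 5.0))
            frac = sub * float(rng.uniform(1.0, 4.0))
            dataset.add_sample(
                Sample(sample_id=sid, haul_id=haul.haul_id, category=cat,
                       subsample_weight=sub, fraction_weight=frac,
                       dp=float(rng.uniform(1.0, 3.0))
                       if cat is Category.DISCARDED else 1.0)
            )
            for code in codes:
                n = int(rng.integers(0, 12))
                rec = registry[code]
                for _ in range(n):
                    L = float(rng.uniform(rec.length_min, rec.length_max))
                    weighed = rng.random() < 0.4
                    dataset.individuals.append(
                        Individual(species_code=code, length=L, sample_id=sid,
                                   weight=rec.a * L ** rec.b if weighed else None,
                                   measured_in="laboratory" if weighed else "field")
                    )
    return dataset
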
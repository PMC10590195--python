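"""Standardized abundance and biomass metrics.

Catch is standardized to densities over the seabed area swept by the gear:

* abundance of species *x*, length class *y*, sample *z* (individuals/km²):

      Abundance_xyz = F_xyz * SP_z * DP_z / (SD * GW)

  where F is the count in the measured subsample, SP the subsample raising
  factor, DP the discard raising factor (1 outside discards), SD the swept
  distance (km) and GW the gear width (km);

* biomass of species *x*, category *k*, sample *z* (kg/km²): the same
  raising applied to the summed individual weights, measured in the
  laboratory or converted from length with W = a L^b;

* group aggregates over a port, area, season or the whole survey:

      Aggr_xy = (1/N) * sum over the NS samples of the group

  with N the number of hauls and NS the number of samples in those hauls —
  so a species absent from a haul still dilutes the average through N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, InvalidInputError, MissingParameterError
from .species import Category, Individual, Sample, SpeciesRecord, TaxonGroup
from .survey import SurveyDataset

__all__ = [
    "DEFAULT_BIN_WIDTHS",
    "LengthClassCount",
    "AggregationResult",
    "bin_width_for",
    "bin_lengths",
    "standardized_abundance",
    "standardized_biomass",
    "abundance_table",
    "biomass_table",
    "aggregate_abundance",
    "aggregate_biomass",
]

#: Length-class width (cm) per taxon group.  Crustaceans are measured at a
#: finer resolution because their size range is narrow.
DEFAULT_BIN_WIDTHS: dict[TaxonGroup, float] = {
    TaxonGroup.FISH: 1.0,
    TaxonGroup.CEPHALOPOD: 1.0,
    TaxonGroup.CRUSTACEAN: 0.5,
    TaxonGroup.OTHER: 1.0,
}

GROUPINGS: dict[str, list[str]] = {
    "all": [],
    "port": ["port"],
    "area": ["area"],
    "season": ["season"],
    "year_season": ["year", "season"],
}


@dataclass(frozen=True)
class LengthClassCount:
    """Count of individuals of one species in one half-open length bin."""

    species_code: str
    length_class: float  # lower bound (cm) of [class, class + width)
    count: int
    sample_id: str


@dataclass(frozen=True)
class AggregationResult:
    """One group of an Eq-3/Eq-4 style aggregation.

    ``values`` is a tidy frame (species_code, length_class-or-category,
    value); each value is the group sample sum divided by ``n_hauls``.
    """

    key: tuple
    n_hauls: int
    n_samples: int
    values: pd.DataFrame


def bin_width_for(group: TaxonGroup, widths: Mapping[TaxonGroup, float] | None = None) -> float:
    table = DEFAULT_BIN_WIDTHS if widths is None else widths
    return table[group]


def bin_lengths(
    individuals: Iterable[Individual], bin_width: float
) -> list[LengthClassCount]:
    """Assign individuals to half-open length bins [m*w, (m+1)*w).

    Counts are per (species, bin, sample); the total count is preserved.
    """
    if not bin_width > 0:
        raise ConfigError(f"bin width must be positive, got {bin_width}")
    counts: dict[tuple[str, float, str], int] = {}
    for ind in individuals:
        lower = math.floor(ind.length / bin_width + 1e-12) * bin_width
        key = (ind.species_code, round(lower, 10), ind.sample_id)
        counts[key] = counts.get(key, 0) + 1
    return [
        LengthClassCount(species_code=sp, length_class=lc, count=n, sample_id=sid)
        for (sp, lc, sid), n in sorted(counts.items())
    ]


def standardized_abundance(
    count: float, sp: float, dp: float, sd_km: float, gw_km: float
) -> float:
    """Abundance (individuals/km²) = F * SP * DP / (SD * GW)."""
    if not (sd_km > 0 and gw_km > 0):
        raise InvalidInputError(
            f"degenerate haul: swept distance {sd_km} km x gear width {gw_km} km"
        )
    if count < 0 or sp < 1 or dp < 1:
        raise InvalidInputError("need count >= 0 and raising factors >= 1")
    return count * sp * dp / (sd_km * gw_km)


def standardized_biomass(
    individuals: Sequence[Individual],
    species: SpeciesRecord | None,
    sample: Sample,
    sd_km: float,
    gw_km: float,
) -> float:
    """Biomass (kg/km²) of one species in one sample.

    Laboratory individuals contribute their measured weight; field individuals
    are converted from length with the species' W = a L^b (grams).  Litter and
    debris items must always carry measured weights.
    """
    if not (sd_km > 0 and gw_km > 0):
        raise InvalidInputError(
            f"degenerate haul: swept distance {sd_km} km x gear width {gw_km} km"
        )
    total_g = 0.0
    for ind in individuals:
        if ind.weight is not None:
            total_g += ind.weight
        else:
            if species is None:
                raise MissingParameterError(
                    f"species {ind.species_code!r} lacks length-weight parameters "
                    "needed to convert a field-measured individual"
                )
            total_g += species.a * ind.length ** species.b
    return (total_g / 1000.0) * sample.sp * sample.dp / (sd_km * gw_km)


def abundance_table(
    dataset: SurveyDataset,
    bin_widths: Mapping[TaxonGroup, float] | None = None,
) -> pd.DataFrame:
    """Per-sample standardized abundance by length class for a whole dataset.

    Returns a tidy frame with columns species_code, length_class, sample_id,
    haul_id, value (individuals/km²), units.
    """
    rows: list[dict] = []
    by_sample = dataset.individuals_by_sample()
    for sample_id, inds in by_sample.items():
        sample = dataset.samples[sample_id]
        haul = dataset.hauls[sample.haul_id]
        gw_km = haul.gear_width_m / 1000.0
        by_species: dict[str, list[Individual]] = {}
        for ind in inds:
            by_species.setdefault(ind.species_code, []).append(ind)
        for code, sp_inds in by_species.items():
            rec = dataset.registry.get(code)
            width = bin_width_for(rec.group if rec else TaxonGroup.OTHER, bin_widths)
            for lcc in bin_lengths(sp_inds, width):
                rows.append(
                    {
                        "species_code": code,
                        "length_class": lcc.length_class,
                        "sample_id": sample_id,
                        "haul_id": haul.haul_id,
                        "value": standardized_abundance(
                            lcc.count, sample.sp, sample.dp,
                            haul.swept_distance_km, gw_km,
                        ),
                        "units": "individuals/km2",
                    }
                )
    cols = ["species_code", "length_class", "sample_id", "haul_id", "value", "units"]
    return pd.DataFrame(rows, columns=cols).sort_values(
        ["species_code", "length_class", "sample_id"], ignore_index=True
    )


def biomass_table(dataset: SurveyDataset) -> pd.DataFrame:
    """Per-sample standardized biomass by category (kg/km²) for a dataset."""
    rows: list[dict] = []
    by_sample = dataset.individuals_by_sample()
    for sample_id, inds in by_sample.items():
        sample = dataset.samples[sample_id]
        haul = dataset.hauls[sample.haul_id]
        gw_km = haul.gear_width_m / 1000.0
        by_species: dict[str, list[Individual]] = {}
        for ind in inds:
            by_species.setdefault(ind.species_code, []).append(ind)
        for code, sp_inds in by_species.items():
            rows.append(
                {
                    "species_code": code,
                    "category": sample.category.value,
                    "sample_id": sample_id,
                    "haul_id": haul.haul_id,
                    "value": standardized_biomass(
                        sp_inds, dataset.registry.get(code), sample,
                        haul.swept_distance_km, gw_km,
                    ),
                    "units": "kg/km2",
                }
            )
    cols = ["species_code", "category", "sample_id", "haul_id", "value", "units"]
    return pd.DataFrame(rows, columns=cols).sort_values(
        ["species_code", "category", "sample_id"], ignore_index=True
    )


def _aggregate(
    per_sample: pd.DataFrame,
    dataset: SurveyDataset,
    by: str,
    value_keys: list[str],
) -> list[AggregationResult]:
    if by not in GROUPINGS:
        raise ConfigError(f"unknown grouping {by!r}; expected one of {sorted(GROUPINGS)}")
    group_cols = GROUPINGS[by]
    hauls = dataset.hauls_table()
    samples = dataset.samples_table()
    if hauls.empty:
        return []
    if group_cols:
        grouped_hauls = hauls.groupby(group_cols, sort=True)
    else:
        grouped_hauls = [((), hauls)]

    results: list[AggregationResult] = []
    for key, hgroup in grouped_hauls:
        if not isinstance(key, tuple):
            key = (key,)
        haul_ids = set(hgroup["haul_id"])
        n_hauls = len(haul_ids)
        group_samples = samples[samples["haul_id"].isin(haul_ids)]
        n_samples = group_samples["sample_id"].nunique()
        sub = per_sample[per_sample["haul_id"].isin(haul_ids)]
        if sub.empty:
            values = pd.DataFrame(columns=value_keys + ["value"])
        else:
            values = (
                sub.groupby(value_keys, sort=True)["value"].sum().div(n_hauls)
            ).reset_index()
        results.append(
            AggregationResult(
                key=key, n_hauls=n_hauls, n_samples=int(n_samples), values=values
            )
        )
    return results


def aggregate_abundance(
    per_sample: pd.DataFrame, dataset: SurveyDataset, by: str = "all"
) -> list[AggregationResult]:
    """Aggregate per-sample abundances: (1/N) * sum over group samples,
    per (species, length class)."""
    return _aggregate(per_sample, dataset, by, ["species_code", "length_class"])


def aggregate_biomass(
    per_sample: pd.DataFrame, dataset: SurveyDataset, by: str = "all"
) -> list[AggregationResult]:
    """Aggregate per-sample biomass: (1/N) * sum over group samples,
    per (species, category)."""
    return _aggregate(per_sample, dataset, by, ["species_code", "category"])
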
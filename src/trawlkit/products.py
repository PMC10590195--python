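"""Exportable data products: length-frequency series, 4-level catch
composition trees, and per-haul geolocation documents.

Products are pure functions of the standardized-metric tables and are
serialized as static JSON / GeoJSON / CSV with numbers rounded to 6
significant digits, so rebuilding from the same tables is byte-identical.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ConfigError, UnknownEntityError
from .standardize import (
    abundance_table,
    aggregate_abundance,
    aggregate_biomass,
    biomass_table,
)
from .survey import SurveyDataset

__all__ = [
    "LengthFrequencySeries",
    "CompositionNode",
    "build_length_frequency",
    "build_catch_composition",
    "build_haul_geolocation",
    "composition_to_csv",
    "round_sig",
]

SIG_DIGITS = 6


def round_sig(x: float, digits: int = SIG_DIGITS) -> float:
    """Round to ``digits`` significant digits (0 stays 0)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, digits - 1 - int(math.floor(math.log10(abs(x)))))


@dataclass(frozen=True)
class LengthFrequencySeries:
    """Aggregated abundance (individuals/km²) per length class for one species."""

    species_code: str
    pairs: tuple[tuple[float, float], ...]  # (length_class_cm, abundance) ascending

    def to_dict(self) -> dict:
        return {
            "species_code": self.species_code,
            "length_classes_cm": [p[0] for p in self.pairs],
            "abundance_per_km2": [round_sig(p[1]) for p in self.pairs],
        }


@dataclass
class CompositionNode:
    """Node of the 4-level catch-composition tree.

    Levels run area → port → category → species (port mode) or
    year → season → category → species (season mode); every non-leaf value
    equals the sum of its children.
    """

    label: str
    level: str
    value: float = 0.0
    children: list["CompositionNode"] = field(default_factory=list)

    def to_dict(self) -> dict:
        d: dict = {"label": self.label, "level": self.level,
                   "value": round_sig(self.value)}
        if self.children:
            d["children"] = [c.to_dict() for c in self.children]
        return d

    def leaves(self) -> list["CompositionNode"]:
        if not self.children:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


def build_length_frequency(
    dataset: SurveyDataset,
    species: Sequence[str] | None = None,
    by: str = "all",
    per_sample: pd.DataFrame | None = None,
) -> list[LengthFrequencySeries]:
    """One aggregated length-frequency series per requested species.

    By default aggregates over all areas and years; ``by`` accepts the same
    groupings as the standardization stage (only "all" yields one series per
    species; other groupings use the first group).
    """
    if per_sample is None:
        per_sample = abundance_table(dataset)
    if species:
        unknown = [s for s in species if s not in dataset.registry]
        if unknown:
            raise UnknownEntityError(f"unknown species in filter: {unknown}")
    results = aggregate_abundance(per_sample, dataset, by=by)
    if not results:
        return []
    values = results[0].values
    codes = species or sorted(values["species_code"].unique())
    series = []
    for code in codes:
        sub = values[values["species_code"] == code].sort_values("length_class")
        series.append(
            LengthFrequencySeries(
                species_code=code,
                pairs=tuple(
                    (float(r.length_class), float(r.value))
                    for r in sub.itertuples(index=False)
                ),
            )
        )
    return series


def build_catch_composition(
    dataset: SurveyDataset,
    mode: str = "port",
    species: Sequence[str] | None = None,
    per_sample: pd.DataFrame | None = None,
) -> CompositionNode:
    """Build the 4-level composition tree with group-averaged biomass leaves.

    A leaf (group, category, species) carries the aggregate biomass of that
    species/category over the group's hauls; internal nodes sum their
    children, up to a single root spanning the whole survey.
    """
    if mode not in ("port", "season"):
        raise ConfigError(f"mode must be 'port' or 'season', got {mode!r}")
    if per_sample is None:
        per_sample = biomass_table(dataset)
    if species:
        unknown = [s for s in species if s not in dataset.registry]
        if unknown:
            raise UnknownEntityError(f"unknown species in filter: {unknown}")
        per_sample = per_sample[per_sample["species_code"].isin(species)]

    hauls = dataset.hauls_table()
    if mode == "port":
        level1, level2 = "area", "port"
        groups = aggregate_biomass(per_sample, dataset, by="port")
        parent_of = dict(zip(hauls["port"], hauls["area"]))
        key_label = {r.key[0]: r.key[0] for r in groups}
    else:
        level1, level2 = "year", "season"
        groups = aggregate_biomass(per_sample, dataset, by="year_season")
        parent_of = {}
        key_label = {}

    root = CompositionNode(label="total", level="root")
    level1_nodes: dict[str, CompositionNode] = {}
    for res in groups:
        if mode == "port":
            port = res.key[0]
            l1_label, l2_label = parent_of[port], port
        else:
            year, seas = res.key
            l1_label, l2_label = str(year), seas
        if l1_label not in level1_nodes:
            node = CompositionNode(label=l1_label, level=level1)
            level1_nodes[l1_label] = node
            root.children.append(node)
        l1 = level1_nodes[l1_label]
        l2 = CompositionNode(label=l2_label, level=level2)
        l1.children.append(l2)
        cat_nodes: dict[str, CompositionNode] = {}
        for row in res.values.sort_values(["category", "species_code"]).itertuples(index=False):
            if row.category not in cat_nodes:
                cat = CompositionNode(label=row.category, level="category")
                cat_nodes[row.category] = cat
                l2.children.append(cat)
            leaf = CompositionNode(label=row.species_code, level="species",
                                   value=float(row.value))
            cat_nodes[row.category].children.append(leaf)
        for cat in cat_nodes.values():
            cat.value = sum(c.value for c in cat.children)
        l2.value = sum(c.value for c in l2.children)
    for l1 in root.children:
        l1.value = sum(c.value for c in l1.children)
    root.value = sum(c.value for c in root.children)
    # stable ordering for byte-identical artifacts
    root.children.sort(key=lambda n: n.label)
    for l1 in root.children:
        l1.children.sort(key=lambda n: n.label)
    return root


def composition_to_csv(root: CompositionNode) -> pd.DataFrame:
    """Flatten tree leaves into the downloadable pie-chart CSV."""
    rows = []

    def walk(node: CompositionNode, path: tuple[str, ...]) -> None:
        if not node.children:
            rows.append(dict(zip(
                ("level1", "level2", "category", "species"), path
            )) | {"value_kg_per_km2": round_sig(node.value)})
            return
        for c in node.children:
            walk(c, path + (c.label,))

    for c in root.children:
        walk(c, (c.label,))
    return pd.DataFrame(rows, columns=["level1", "level2", "category", "species",
                                       "value_kg_per_km2"])


def build_haul_geolocation(
    dataset: SurveyDataset,
    haul_id: str,
    per_sample: pd.DataFrame | None = None,
) -> dict:
    """GeoJSON Feature for one haul: track LineString plus its catch
    composition (kg/km² per category and species), depth, duration, date."""
    haul = dataset.hauls.get(haul_id)
    if haul is None:
        raise UnknownEntityError(f"haul {haul_id!r} not in dataset")
    if haul.track is None:
        raise UnknownEntityError(f"haul {haul_id!r} has no cut track")
    if per_sample is None:
        per_sample = biomass_table(dataset)
    rows = per_sample[per_sample["haul_id"] == haul_id]
    composition = {}
    for row in rows.sort_values(["category", "species_code"]).itertuples(index=False):
        composition.setdefault(row.category, {})[row.species_code] = round_sig(
            composition.get(row.category, {}).get(row.species_code, 0.0) + row.value
        )
    feature = haul.track.to_geojson()
    feature["properties"].update(
        {
            "haul_id": haul.haul_id,
            "date": haul.date.isoformat(),
            "port": haul.port,
            "area": haul.area,
            "season": haul.season,
            "average_depth_m": haul.depth_stratum_m,
            "duration_min": round_sig(haul.track.duration_minutes),
            "swept_area_km2": round_sig(haul.swept_area_km2),
            "composition_kg_per_km2": composition,
        }
    )
    return feature


def write_products(
    dataset: SurveyDataset, out_dir: str | Path,
    species: Sequence[str] | None = None,
) -> list[Path]:
    """Write the three static products for a dataset; returns written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    series = build_length_frequency(dataset, species=species)
    p = out / "length_frequency.json"
    p.write_text(json.dumps([s.to_dict() for s in series], indent=2))
    written.append(p)

    for mode in ("port", "season"):
        tree = build_catch_composition(dataset, mode=mode, species=species)
        p = out / f"composition_{mode}.json"
        p.write_text(json.dumps(tree.to_dict(), indent=2))
        written.append(p)
        p = out / f"composition_{mode}.csv"
        composition_to_csv(tree).to_csv(p, index=False)
        written.append(p)

    per_sample = biomass_table(dataset)
    features = [
        build_haul_geolocation(dataset, hid, per_sample=per_sample)
        for hid in sorted(dataset.hauls)
    ]
    p = out / "haul_geolocation.geojson"
    p.write_text(json.dumps({"type": "FeatureCollection", "features": features},
                            indent=2))
    written.append(p)
    return written
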
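"""Species registry, individuals and samples, and the length-weight relationship.

The allometric model W = a * L^b converts a measured length L (cm) into a wet
weight (grams).  ``a`` and ``b`` are species parameters, calibrated here by
ordinary least squares on the log-log transformed laboratory measurements:

    log W = log a + b * log L

Weights are carried in grams because length-weight literature conventionally
reports ``a`` for gram/cm calibrations; downstream biomass code converts to kg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    InconsistencyError,
    InsufficientDataError,
    InvalidInputError,
    UnknownEntityError,
)

__all__ = [
    "Category",
    "TaxonGroup",
    "SpeciesRecord",
    "SpeciesRegistry",
    "Individual",
    "Sample",
    "LWFit",
    "length_to_weight",
    "fit_length_weight",
    "raising_factor",
]


class Category(str, Enum):
    """Catch fraction a sorted sample belongs to."""

    LANDED = "landed"
    DISCARDED = "discarded"
    NATURAL_DEBRIS = "natural_debris"
    MARINE_LITTER = "marine_litter"


class TaxonGroup(str, Enum):
    FISH = "fish"
    CRUSTACEAN = "crustacean"
    CEPHALOPOD = "cephalopod"
    OTHER = "other"


@dataclass(frozen=True)
class SpeciesRecord:
    """Registry entry for one taxon.

    Parameters
    ----------
    code : str
        Short unique identifier (e.g. FAO 3-alpha code).
    a, b : float
        Length-weight parameters for W[g] = a * L[cm]**b.
    length_min, length_max : float
        Usual length range in cm, used by QC range checks.
    mcrs : float or None
        Minimum conservation reference size in cm, if regulated.
    group : TaxonGroup
        Coarse taxon group; controls the default length-class width.
    """

    code: str
    scientific_name: str
    a: float
    b: float
    length_min: float
    length_max: float
    mcrs: float | None = None
    group: TaxonGroup = TaxonGroup.FISH

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise InvalidInputError(
                f"species {self.code}: length-weight parameters must be positive "
                f"(a={self.a}, b={self.b})"
            )
        if not self.length_min < self.length_max:
            raise InvalidInputError(
                f"species {self.code}: length_min must be below length_max"
            )
        if self.mcrs is not None and not (0 <= self.mcrs <= self.length_max):
            raise InvalidInputError(
                f"species {self.code}: mcrs={self.mcrs} outside [0, length_max]"
            )


class SpeciesRegistry:
    """Lookup table of :class:`SpeciesRecord` keyed by species code."""

    def __init__(self, records: Iterable[SpeciesRecord] = ()) -> None:
        self._records: dict[str, SpeciesRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, record: SpeciesRecord) -> None:
        if record.code in self._records:
            raise InconsistencyError(f"duplicate species code {record.code!r}")
        self._records[record.code] = record

    def __getitem__(self, code: str) -> SpeciesRecord:
        try:
            return self._records[code]
        except KeyError:
            raise UnknownEntityError(f"species {code!r} not registered") from None

    def __contains__(self, code: str) -> bool:
        return code in self._records

    def __iter__(self):
        return iter(self._records.values())

    def __len__(self) -> int:
        return len(self._records)

    def get(self, code: str) -> SpeciesRecord | None:
        return self._records.get(code)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpeciesRegistry":
        """Read a registry CSV with columns
        code, scientific_name, a, b, length_min_cm, length_max_cm, mcrs_cm, group."""
        df = pd.read_csv(path)
        required = {"code", "scientific_name", "a", "b", "length_min_cm", "length_max_cm"}
        missing = required - set(df.columns)
        if missing:
            raise InvalidInputError(f"registry CSV missing columns: {sorted(missing)}")
        records = []
        for row in df.itertuples(index=False):
            mcrs = getattr(row, "mcrs_cm", None)
            if mcrs is not None and (pd.isna(mcrs)):
                mcrs = None
            group = getattr(row, "group", "fish")
            records.append(
                SpeciesRecord(
                    code=str(row.code),
                    scientific_name=str(row.scientific_name),
                    a=float(row.a),
                    b=float(row.b),
                    length_min=float(row.length_min_cm),
                    length_max=float(row.length_max_cm),
                    mcrs=None if mcrs is None else float(mcrs),
                    group=TaxonGroup(group),
                )
            )
        return cls(records)

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {
                "code": r.code,
                "scientific_name": r.scientific_name,
                "a": r.a,
                "b": r.b,
                "length_min_cm": r.length_min,
                "length_max_cm": r.length_max,
                "mcrs_cm": r.mcrs,
                "group": r.group.value,
            }
            for r in self
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


@dataclass(frozen=True)
class Individual:
    """One measured animal (or litter/debris item) in a sample.

    ``weight`` (grams) is present for laboratory-measured individuals; field
    individuals carry length only and are converted via the length-weight
    relationship.
    """

    species_code: str
    length: float  # cm
    sample_id: str
    weight: float | None = None  # grams
    measured_in: str = "field"  # "field" | "laboratory"

    def __post_init__(self) -> None:
        if not self.length > 0:
            raise InvalidInputError(f"length must be positive, got {self.length}")
        if self.weight is not None and not self.weight > 0:
            raise InvalidInputError(f"weight must be positive, got {self.weight}")
        if self.measured_in not in ("field", "laboratory"):
            raise InvalidInputError(f"measured_in must be field|laboratory, got {self.measured_in!r}")


@dataclass(frozen=True)
class Sample:
    """One sorted catch fraction of a haul, with its raising factors.

    ``sp`` raises the measured subsample up to the whole fraction
    (fraction_weight / subsample_weight, >= 1).  ``dp`` raises the sorted
    discard subsample up to the whole discarded fraction and is 1 for every
    other category.
    """

    sample_id: str
    haul_id: str
    category: Category
    subsample_weight: float  # kg
    fraction_weight: float  # kg
    sp: float | None = None
    dp: float = 1.0

    def __post_init__(self) -> None:
        if self.subsample_weight > self.fraction_weight:
            raise InconsistencyError(
                f"sample {self.sample_id}: subsample ({self.subsample_weight} kg) "
                f"exceeds fraction ({self.fraction_weight} kg)"
            )
        if self.sp is None:
            object.__setattr__(
                self, "sp", raising_factor(self.subsample_weight, self.fraction_weight)
            )
        if self.dp < 1:
            raise InvalidInputError(f"sample {self.sample_id}: dp must be >= 1")
        if self.category is not Category.DISCARDED and self.dp != 1.0:
            raise InconsistencyError(
                f"sample {self.sample_id}: dp != 1 only allowed for discards"
            )


@dataclass(frozen=True)
class LWFit:
    """Result of a log-log length-weight regression."""

    species_code: str
    a: float
    b: float
    r_squared: float
    n_points: int
    residual_sd_loglog: float

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise InsufficientDataError("length-weight fit needs >= 3 points")
        if not self.a > 0:
            raise InvalidInputError("fitted a must be positive")

    def predict(self, length: float) -> float:
        """Predicted weight (g) at ``length`` (cm)."""
        if not length > 0:
            raise InvalidInputError(f"length must be positive, got {length}")
        return self.a * length ** self.b


def length_to_weight(length: float, species: SpeciesRecord | LWFit) -> float:
    """Convert a length (cm) to weight (g) with the species' W = a L^b.

    Raises :class:`InvalidInputError` for non-positive lengths.
    """
    if not length > 0:
        raise InvalidInputError(f"length must be positive, got {length}")
    return species.a * length ** species.b


def fit_length_weight(
    pairs: Sequence[tuple[float, float]] | np.ndarray,
    species_code: str = "",
) -> LWFit:
    """Fit W = a L^b by OLS on log W = log a + b log L.

    Parameters
    ----------
    pairs : sequence of (length_cm, weight_g)
        Laboratory measurements; at least 3 pairs with at least 2 distinct
        lengths, all strictly positive.

    Returns
    -------
    LWFit with back-transformed ``a``, exponent ``b``, R², and the residual
    standard deviation on the log-log scale (used by outlier QC).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise InsufficientDataError(
            f"need >= 3 (length, weight) pairs, got {0 if arr.ndim != 2 else arr.shape[0]}"
        )
    if np.any(arr <= 0):
        raise InvalidInputError("lengths and weights must all be positive")
    lengths, weights = arr[:, 0], arr[:, 1]
    if np.unique(lengths).size < 2:
        raise InsufficientDataError("all lengths identical; exponent not identifiable")

    x = np.log(lengths)
    y = np.log(weights)
    # slope = b, intercept = log a
    b, log_a = np.polyfit(x, y, 1)
    resid = y - (log_a + b * x)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    dof = max(len(y) - 2, 1)
    return LWFit(
        species_code=species_code,
        a=float(math.exp(log_a)),
        b=float(b),
        r_squared=float(r2),
        n_points=int(len(y)),
        residual_sd_loglog=float(math.sqrt(ss_res / dof)),
    )


def raising_factor(subsample_weight: float, fraction_weight: float) -> float:
    """Raising factor SP = fraction_weight / subsample_weight (>= 1).

    Scales counts from a measured subsample up to the whole sorted fraction;
    1.0 when the entire fraction was measured.
    """
    if not (subsample_weight > 0 and fraction_weight > 0):
        raise InvalidInputError("weights must be positive")
    if subsample_weight > fraction_weight:
        raise InconsistencyError(
            f"subsample ({subsample_weight}) exceeds fraction ({fraction_weight})"
        )
    return fraction_weight / subsample_weight
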
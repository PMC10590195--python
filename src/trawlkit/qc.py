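"""Data-entry validation: range checks, length-weight outliers, completeness.

Mirrors the human-in-the-loop validation of the survey data entry: checks
never mutate the data, they only emit issues.  Range and MCRS violations are
warnings (extreme but true values exist); broken references and impossible
weights are errors.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

from .species import Individual, LWFit, SpeciesRecord, SpeciesRegistry
from .survey import SurveyDataset

__all__ = [
    "Severity",
    "ValidationIssue",
    "validate_length",
    "flag_lw_outliers",
    "completeness_check",
    "validate_dataset",
    "write_report_csv",
    "write_report_json",
]

log = logging.getLogger(__name__)

WARNING = "warning"
ERROR = "error"
Severity = str

#: Default residual threshold, in log-scale standard deviations, above which
#: a weighed individual is flagged against the fitted length-weight line.
DEFAULT_OUTLIER_SD = 3.0


@dataclass(frozen=True)
class ValidationIssue:
    severity: Severity
    rule_id: str
    table: str
    row: str
    message: str

    def as_dict(self) -> dict:
        return asdict(self)


def validate_length(
    individual: Individual, species: SpeciesRecord | None
) -> list[ValidationIssue]:
    """Check one individual's length against the species' usual range and MCRS.

    An unregistered species yields an error-severity issue, not an exception.
    """
    loc = f"{individual.sample_id}/{individual.species_code}"
    if species is None:
        return [
            ValidationIssue(
                ERROR, "unregistered-species", "individuals", loc,
                f"species {individual.species_code!r} is not in the registry",
            )
        ]
    issues: list[ValidationIssue] = []
    if not (species.length_min <= individual.length <= species.length_max):
        issues.append(
            ValidationIssue(
                WARNING, "length-out-of-range", "individuals", loc,
                f"length {individual.length} cm outside usual range "
                f"[{species.length_min}, {species.length_max}] cm for {species.code}",
            )
        )
    if species.mcrs is not None and individual.length < species.mcrs:
        issues.append(
            ValidationIssue(
                WARNING, "below-mcrs", "individuals", loc,
                f"length {individual.length} cm below MCRS {species.mcrs} cm "
                f"for {species.code}",
            )
        )
    return issues


def flag_lw_outliers(
    individuals: Sequence[Individual], fit: LWFit, k: float = DEFAULT_OUTLIER_SD
) -> list[ValidationIssue]:
    """Flag weighed individuals whose log-weight residual from the fitted
    log-log line exceeds ``k`` residual standard deviations."""
    if not k > 0:
        raise ValueError(f"k must be positive, got {k}")
    weighed = [i for i in individuals if i.weight is not None]
    if not weighed:
        log.info("no weighed individuals to check against the length-weight fit")
        return []
    # floor guards against flagging rounding noise on an exact fit
    threshold = max(k * fit.residual_sd_loglog, 1e-9)
    issues = []
    for idx, ind in enumerate(weighed):
        resid = abs(math.log(ind.weight) - math.log(fit.predict(ind.length)))
        if resid > threshold:
            issues.append(
                ValidationIssue(
                    WARNING, "length-weight-outlier", "individuals",
                    f"{ind.sample_id}/{ind.species_code}#{idx}",
                    f"log-weight residual {resid:.3f} exceeds {k} x sd "
                    f"({fit.residual_sd_loglog:.3f}) for {ind.species_code}",
                )
            )
    return issues


def completeness_check(dataset: SurveyDataset) -> list[ValidationIssue]:
    """Cross-table referential and geometry checks over a whole dataset."""
    issues: list[ValidationIssue] = []
    for haul in dataset.hauls.values():
        if haul.track is None or len(haul.track) == 0:
            issues.append(
                ValidationIssue(ERROR, "haul-missing-track", "hauls", haul.haul_id,
                                f"haul {haul.haul_id} has no GPS track")
            )
        if len(haul.onboard_positions) < 2:
            issues.append(
                ValidationIssue(ERROR, "haul-missing-onboard", "hauls", haul.haul_id,
                                f"haul {haul.haul_id} has fewer than 2 onboard positions")
            )
        if haul.swept_area_km2 <= 0:
            issues.append(
                ValidationIssue(ERROR, "haul-zero-swept-area", "hauls", haul.haul_id,
                                f"haul {haul.haul_id} has swept area <= 0")
            )
    for sample in dataset.samples.values():
        if sample.haul_id not in dataset.hauls:
            issues.append(
                ValidationIssue(ERROR, "sample-missing-haul", "samples", sample.sample_id,
                                f"sample {sample.sample_id} references missing haul "
                                f"{sample.haul_id!r}")
            )
        if sample.subsample_weight > sample.fraction_weight:
            issues.append(
                ValidationIssue(ERROR, "subsample-exceeds-fraction", "samples",
                                sample.sample_id,
                                f"sample {sample.sample_id}: subsample weight exceeds "
                                "fraction weight")
            )
    for idx, ind in enumerate(dataset.individuals):
        if ind.sample_id not in dataset.samples:
            issues.append(
                ValidationIssue(ERROR, "individual-missing-sample", "individuals",
                                f"row {idx}",
                                f"individual references missing sample {ind.sample_id!r}")
            )
    return issues


def validate_dataset(
    dataset: SurveyDataset, outlier_sd: float = DEFAULT_OUTLIER_SD
) -> list[ValidationIssue]:
    """Full QC pass: completeness, per-individual length/MCRS checks, and
    length-weight outliers per species (where >= 3 weighed individuals)."""
    issues = completeness_check(dataset)
    for ind in dataset.individuals:
        issues.extend(validate_length(ind, dataset.registry.get(ind.species_code)))

    from .species import fit_length_weight  # local to avoid cycle in docs builds

    weighed_by_species: dict[str, list[Individual]] = {}
    for ind in dataset.individuals:
        if ind.weight is not None:
            weighed_by_species.setdefault(ind.species_code, []).append(ind)
    for code, inds in weighed_by_species.items():
        lengths = {i.length for i in inds}
        if len(inds) < 3 or len(lengths) < 2:
            continue
        fit = fit_length_weight([(i.length, i.weight) for i in inds], species_code=code)
        issues.extend(flag_lw_outliers(inds, fit, k=outlier_sd))
    return issues


def write_report_csv(issues: Iterable[ValidationIssue], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["severity", "rule_id", "table", "row", "message"]
        )
        writer.writeheader()
        for issue in issues:
            writer.writerow(issue.as_dict())


def write_report_json(issues: Iterable[ValidationIssue], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([i.as_dict() for i in issues], fh, indent=2)
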
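"""Validation-status classification against deep-resequencing data.

Candidate somatic mutations are checked against independently generated
validation sequencing of the same tumor and normal samples.  The decision
grid works on the variant allele fractions observed in the validation
data:

======================  ==========  =========  ==============  ==========
Normal VAF              Tumor 0%    Tumor <8%  Tumor >=8,<20%  Tumor >=20%
======================  ==========  =========  ==============  ==========
exactly 0%              NotValid.   SomaticLow SomaticMed      SomaticHigh
>0%, <3%                NotValid.   Ambiguous  SomaticMed      SomaticHigh
>=3%                    Germline/LOH across the whole row
======================  ==========  =========  ==============  ==========

A call with fewer than 10 validation reads in either sample is Ambiguous
regardless of VAFs.  "Exactly 0%" means zero alt-supporting reads.

One database-rescue rule applies: a *Not Validated* RNA-rescued call whose
position matches a catalogued somatic mutation confirmed in another study
is accepted as validated (at the lowest somatic tier).

Precision is reported per call group as
``validated / (validated + notValidated + germlineLOH)``; Ambiguous calls
are excluded from the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .calling import VariantCall
from .region_annotations import RegionSet

__all__ = [
    "ValidationObservation",
    "ValidationStatus",
    "classify_validation",
    "cosmic_rescue",
    "precision_report",
    "GroupReport",
]


class ValidationStatus(Enum):
    SOMATIC_LOW = "SomaticLow"
    SOMATIC_MED = "SomaticMed"
    SOMATIC_HIGH = "SomaticHigh"
    GERMLINE_LOH = "GermlineLOH"
    NOT_VALIDATED = "NotValidated"
    AMBIGUOUS = "Ambiguous"

    @property
    def validated(self) -> bool:
        return self in (
            ValidationStatus.SOMATIC_LOW,
            ValidationStatus.SOMATIC_MED,
            ValidationStatus.SOMATIC_HIGH,
        )


@dataclass(frozen=True)
class ValidationObservation:
    """VAFs and depths of one call in the validation sequencing data."""

    normal_vaf: float
    tumor_vaf: float
    normal_depth: int
    tumor_depth: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.normal_vaf <= 1.0 or not 0.0 <= self.tumor_vaf <= 1.0:
            raise ValueError("VAFs must lie in [0, 1]")
        if self.normal_depth < 0 or self.tumor_depth < 0:
            raise ValueError("depths must be non-negative")


def classify_validation(
    v: ValidationObservation, min_depth: int = 10
) -> ValidationStatus:
    """Place one validation observation in the decision grid above."""
    if v.normal_depth < min_depth or v.tumor_depth < min_depth:
        return ValidationStatus.AMBIGUOUS
    if v.normal_vaf >= 0.03:
        return ValidationStatus.GERMLINE_LOH
    if v.tumor_vaf == 0.0:
        return ValidationStatus.NOT_VALIDATED
    if v.tumor_vaf >= 0.20:
        return ValidationStatus.SOMATIC_HIGH
    if v.tumor_vaf >= 0.08:
        return ValidationStatus.SOMATIC_MED
    # tumor VAF in (0, 8%)
    if v.normal_vaf == 0.0:
        return ValidationStatus.SOMATIC_LOW
    return ValidationStatus.AMBIGUOUS  # low but non-zero in both samples


def cosmic_rescue(
    status: ValidationStatus, call: VariantCall, cosmic: RegionSet | None
) -> ValidationStatus:
    """Rescue a Not-Validated RNA-rescued call at a catalogued somatic
    mutation position; every other status passes through unchanged."""
    if (
        status is ValidationStatus.NOT_VALIDATED
        and call.label == "RNA_Rescue"
        and cosmic is not None
        and cosmic.contains(call.chrom, call.pos)
    ):
        return ValidationStatus.SOMATIC_LOW
    return status


@dataclass(frozen=True)
class GroupReport:
    """Validation accounting for one group of calls."""

    group: str
    validated: int
    not_validated: int
    germline_loh: int
    ambiguous: int

    @property
    def total(self) -> int:
        return self.validated + self.not_validated + self.germline_loh + self.ambiguous

    @property
    def precision(self) -> float | None:
        """validated / (validated + notValidated + germlineLOH); ``None``
        when every call is ambiguous."""
        denominator = self.validated + self.not_validated + self.germline_loh
        return self.validated / denominator if denominator else None


def _tally(group: str, statuses: Iterable[ValidationStatus]) -> GroupReport:
    validated = not_validated = germline = ambiguous = 0
    for status in statuses:
        if status.validated:
            validated += 1
        elif status is ValidationStatus.NOT_VALIDATED:
            not_validated += 1
        elif status is ValidationStatus.GERMLINE_LOH:
            germline += 1
        else:
            ambiguous += 1
    return GroupReport(group, validated, not_validated, germline, ambiguous)


def precision_report(
    calls_with_status: Sequence[tuple[VariantCall, ValidationStatus]],
) -> dict[str, GroupReport]:
    """Per-group validation counts and precision.

    Groups: ``all``, the calling paths (``DOM`` = DNA-only or confirmed,
    ``TBM`` = triple-sample or confirmed) and the somatic classes
    (``RNA_Confirmation``, ``RNA_Rescue``, ``DNA_only``).
    """

    def members(predicate) -> list[ValidationStatus]:
        return [s for c, s in calls_with_status if predicate(c)]

    groups: Mapping[str, list[ValidationStatus]] = {
        "all": members(lambda c: True),
        "DOM": members(lambda c: c.origin in ("DOM", "both")),
        "TBM": members(lambda c: c.origin in ("TBM", "both")),
        "RNA_Confirmation": members(lambda c: c.label == "RNA_Confirmation"),
        "RNA_Rescue": members(lambda c: c.label == "RNA_Rescue"),
        "DNA_only": members(lambda c: c.label == "DNA_only"),
    }
    return {name: _tally(name, statuses) for name, statuses in groups.items()}
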
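"""The two calling paths over a pileup column.

**DNA-only path (DOM).**  The matched normal DNA is compared to the
reference first: a site whose normal sample passes the germline threshold
profile is emitted as a germline variant and never tested for a somatic
mutation.  Otherwise the tumor DNA is compared against the normal and the
reference: the tumor must show solid variant support (depth >= 10, >= 4 alt
reads, >= 10% VAF, average alt base quality >= 20, balanced strands) while
the normal must be deep enough to have revealed a germline variant
(depth >= 10) yet carry at most 2% of the candidate allele.

**Triple-sample path (TBM).**  All three samples are consulted.  The
variant allele is taken from the tumor RNA, which must support it strongly
(>= 4 alt reads, >= 10% VAF, average alt base quality >= 15).  The tumor
DNA must contain at least one read carrying the same allele — this is what
separates a rescued low-VAF somatic mutation from a potential RNA-editing
event — and the normal DNA must again be deep and clean.  Sites on the
accessible-genome blacklist, at known-polymorphism positions (current or
retired database versions), or inside pseudogene / high-similarity
gene-family intervals are removed, followed by the positional-bias and
remap checks on the RNA alt reads.

Both evaluators return ``None`` when no lenient candidate exists, and a
:class:`VariantCall` otherwise; the call's verdicts record every failed
filter so rejected candidates can be tallied per filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .detection import DetectionParams, detect_candidate
from .filters import (
    FilterVerdict,
    RemapAligner,
    ThresholdSet,
    apply_thresholds,
    positional_bias_filter,
    remap_check,
)
from .read_model import AlleleSummary, PileupColumn, SampleRole, summarize_column
from .region_annotations import RegionSet

__all__ = [
    "VariantCall",
    "AnnotationSets",
    "DOM_PROFILES",
    "TBM_PROFILES",
    "dom_candidate",
    "tbm_candidate",
    "dom_evaluate",
    "tbm_evaluate",
]

#: DNA-only threshold profiles (germline normal; somatic normal/tumor).
DOM_PROFILES: dict[str, ThresholdSet] = {
    "germline_normal": ThresholdSet(
        name="germline_normal",
        min_total_depth=10,
        min_alt_depth=4,
        min_alt_fraction=0.10,
        min_avg_alt_base_quality=20,
        max_alt_strand_fraction=0.90,
        max_other_fraction=0.02,
    ),
    "somatic_normal": ThresholdSet(
        name="somatic_normal",
        min_total_depth=10,
        max_alt_fraction=0.02,
        max_other_fraction=0.02,
    ),
    "somatic_tumor": ThresholdSet(
        name="somatic_tumor",
        min_total_depth=10,
        min_alt_depth=4,
        min_alt_fraction=0.10,
        min_avg_alt_base_quality=20,
        max_alt_strand_fraction=0.90,
        max_other_fraction=0.02,
    ),
}

#: Triple-sample threshold profiles (one per sample role).
TBM_PROFILES: dict[str, ThresholdSet] = {
    "normal_dna": ThresholdSet(
        name="tbm_normal",
        min_total_depth=10,
        max_alt_fraction=0.10,
        max_other_fraction=0.10,
    ),
    "tumor_dna": ThresholdSet(
        name="tbm_tumor_dna",
        min_total_depth=1,
        min_alt_depth=1,
        min_avg_alt_base_quality=15,
        max_alt_strand_fraction=0.90,
        max_other_fraction=0.10,
    ),
    "tumor_rna": ThresholdSet(
        name="tbm_tumor_rna",
        min_total_depth=10,
        min_alt_depth=4,
        min_alt_fraction=0.10,
        min_avg_alt_base_quality=15,
        max_alt_strand_fraction=0.90,
        max_other_fraction=0.02,
    ),
}


@dataclass
class AnnotationSets:
    """Optional genomic annotations consumed by the filter chains."""

    blacklist: RegionSet | None = None
    dbsnp_common: RegionSet | None = None
    dbsnp_retired: RegionSet | None = None
    pseudogene: RegionSet | None = None
    gene_family: RegionSet | None = None
    cosmic: RegionSet | None = None


@dataclass
class VariantCall:
    """A candidate or final call with its full filtering history."""

    chrom: str
    pos: int  # 0-based internal
    ref: str
    alt: str
    category: str  # "germline" | "somatic"
    origin: str  # "DOM" | "TBM" | "both"
    label: str | None = None  # RNA_Confirmation | RNA_Rescue | DNA_only
    summaries: dict[SampleRole, AlleleSummary] = field(default_factory=dict)
    verdicts: list[FilterVerdict] = field(default_factory=list)

    @property
    def failed_filters(self) -> tuple[str, ...]:
        return tuple(name for v in self.verdicts for name in v.failed_filters)

    @property
    def passed(self) -> bool:
        return not self.failed_filters

    @property
    def filter_field(self) -> str:
        return "PASS" if self.passed else ";".join(self.failed_filters)


def _region_verdict(
    region_set: RegionSet | None, filter_name: str, chrom: str, pos: int
) -> FilterVerdict:
    if region_set is not None and region_set.contains(chrom, pos):
        return FilterVerdict((filter_name,))
    return FilterVerdict()


def dom_candidate(
    column: PileupColumn,
    profiles: Mapping[str, ThresholdSet] = DOM_PROFILES,
    regions: AnnotationSets | None = None,
    detection: DetectionParams = DetectionParams(),
    apply_dbsnp: bool = False,
) -> VariantCall | None:
    """Evaluate the DNA-only path at one column, keeping failed candidates.

    Returns the germline or somatic call (with verdicts, possibly failing)
    or ``None`` when no lenient candidate exists.  A passing germline call
    pre-empts any somatic test at the same column.  ``apply_dbsnp`` extends
    the known-polymorphism filter (normally a triple-sample concern) to
    somatic DNA-only candidates.
    """
    regions = regions or AnnotationSets()

    normal_candidate = detect_candidate(column, SampleRole.NORMAL_DNA, detection)
    germline: VariantCall | None = None
    if normal_candidate is not None and normal_candidate.alt_allele is not None:
        verdicts = [
            _region_verdict(regions.blacklist, "blacklist", column.chrom, column.pos),
            apply_thresholds(normal_candidate, profiles["germline_normal"]),
        ]
        germline = VariantCall(
            chrom=column.chrom,
            pos=column.pos,
            ref=column.ref_base,
            alt=normal_candidate.alt_allele,
            category="germline",
            origin="DOM",
            summaries={SampleRole.NORMAL_DNA: normal_candidate},
            verdicts=verdicts,
        )
        if germline.passed:
            return germline

    tumor_candidate = detect_candidate(column, SampleRole.TUMOR_DNA, detection)
    if tumor_candidate is None or tumor_candidate.alt_allele is None:
        return germline
    alt = tumor_candidate.alt_allele
    normal_summary = summarize_column(
        column.role_observations(SampleRole.NORMAL_DNA),
        column.ref_base,
        min_base_quality=detection.min_base_quality,
        min_map_quality=detection.min_map_quality,
        alt_allele=alt,
    )
    verdicts = [
        _region_verdict(regions.blacklist, "blacklist", column.chrom, column.pos),
    ]
    if apply_dbsnp:
        verdicts.append(
            _region_verdict(regions.dbsnp_common, "dbsnp_common", column.chrom, column.pos)
        )
        verdicts.append(
            _region_verdict(regions.dbsnp_retired, "dbsnp_retired", column.chrom, column.pos)
        )
    verdicts.append(apply_thresholds(normal_summary, profiles["somatic_normal"]))
    verdicts.append(apply_thresholds(tumor_candidate, profiles["somatic_tumor"]))
    return VariantCall(
        chrom=column.chrom,
        pos=column.pos,
        ref=column.ref_base,
        alt=alt,
        category="somatic",
        origin="DOM",
        summaries={
            SampleRole.NORMAL_DNA: normal_summary,
            SampleRole.TUMOR_DNA: tumor_candidate,
        },
        verdicts=verdicts,
    )


def tbm_candidate(
    column: PileupColumn,
    profiles: Mapping[str, ThresholdSet] = TBM_PROFILES,
    regions: AnnotationSets | None = None,
    detection: DetectionParams = DetectionParams(),
    remap_aligner: RemapAligner | None = None,
    positional_bias_threshold: float = 0.95,
) -> VariantCall | None:
    """Evaluate the triple-sample path at one column, keeping failed
    candidates.

    The candidate allele comes from the tumor RNA; the tumor DNA and the
    normal DNA are summarized for that same allele.  The remap check runs
    only when a :class:`RemapAligner` is supplied (it needs stored read
    sequences and candidate regions).
    """
    regions = regions or AnnotationSets()
    rna_candidate = detect_candidate(column, SampleRole.TUMOR_RNA, detection)
    if rna_candidate is None or rna_candidate.alt_allele is None:
        return None
    alt = rna_candidate.alt_allele

    def forced(role: SampleRole) -> AlleleSummary:
        return summarize_column(
            column.role_observations(role),
            column.ref_base,
            min_base_quality=detection.min_base_quality,
            min_map_quality=detection.min_map_quality,
            alt_allele=alt,
        )

    normal_summary = forced(SampleRole.NORMAL_DNA)
    tumor_dna_summary = forced(SampleRole.TUMOR_DNA)

    verdicts = [
        apply_thresholds(normal_summary, profiles["normal_dna"]),
        apply_thresholds(tumor_dna_summary, profiles["tumor_dna"]),
        apply_thresholds(rna_candidate, profiles["tumor_rna"]),
        _region_verdict(regions.dbsnp_common, "dbsnp_common", column.chrom, column.pos),
        _region_verdict(regions.dbsnp_retired, "dbsnp_retired", column.chrom, column.pos),
        _region_verdict(regions.blacklist, "blacklist", column.chrom, column.pos),
        _region_verdict(regions.pseudogene, "pseudogene", column.chrom, column.pos),
        _region_verdict(regions.gene_family, "gene_family", column.chrom, column.pos),
    ]

    rna_alt_obs = [
        o
        for o in column.role_observations(SampleRole.TUMOR_RNA)
        if o.base == alt
        and o.base_quality >= detection.min_base_quality
        and o.map_quality >= detection.min_map_quality
    ]
    verdicts.append(positional_bias_filter(rna_alt_obs, threshold=positional_bias_threshold))
    if remap_aligner is not None:
        verdicts.append(
            remap_check(
                rna_alt_obs,
                column.chrom,
                column.pos,
                remap_aligner,
                total_depth=rna_candidate.depth,
            )
        )

    return VariantCall(
        chrom=column.chrom,
        pos=column.pos,
        ref=column.ref_base,
        alt=alt,
        category="somatic",
        origin="TBM",
        summaries={
            SampleRole.NORMAL_DNA: normal_summary,
            SampleRole.TUMOR_DNA: tumor_dna_summary,
            SampleRole.TUMOR_RNA: rna_candidate,
        },
        verdicts=verdicts,
    )


def dom_evaluate(column: PileupColumn, **kwargs) -> VariantCall | None:
    """DNA-only evaluation: the passing germline or somatic call, or ``None``.

    Keyword arguments are forwarded to :func:`dom_candidate`.
    """
    call = dom_candidate(column, **kwargs)
    return call if call is not None and call.passed else None


def tbm_evaluate(column: PileupColumn, **kwargs) -> VariantCall | None:
    """Triple-sample evaluation: the passing somatic call, or ``None``.

    Keyword arguments are forwarded to :func:`tbm_candidate`.
    """
    call = tbm_candidate(column, **kwargs)
    return call if call is not None and call.passed else None
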
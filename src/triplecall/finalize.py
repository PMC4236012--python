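"""Merging, final read-support filtering, classification and VCF output.

Calls from the DNA-only and triple-sample paths are merged per site:

* made by both paths (same site, same allele) → **RNA_Confirmation**,
  strong DNA and RNA support;
* triple-sample only → **RNA_Rescue**, weak DNA support (at least one alt
  read) but strong RNA support;
* DNA-only path only → **DNA_only**.

Each merged somatic mutation must then be supported by at least four
"perfect" reads — mapping quality >= 10, alt base quality >= 10, the five
flanking base qualities on either side >= 10, properly paired, fewer than
four mismatches across the whole read, and no insertion or deletion in the
alignment — after which the strand-bias rule is re-applied over all perfect
reads (reference- and alt-supporting) at the column: no more than 90% may
come from one strand.

Final calls are written as VCF 4.2 with per-sample depth, allele depth,
allele fraction and average base/mapping qualities.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

from .calling import VariantCall
from .filters import FilterVerdict
from .read_model import PileupColumn, ReadObservation, SampleRole, Strand

__all__ = [
    "PerfectReadParams",
    "is_perfect_read",
    "read_support_filter",
    "merge_calls",
    "write_vcf",
    "format_vaf_percent",
    "filter_report",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PerfectReadParams:
    min_map_quality: int = 10
    min_alt_base_quality: int = 10
    min_flank_quality: int = 10
    max_mismatches: int = 4  # exclusive: a perfect read has fewer than this
    require_proper_pair: bool = True
    forbid_indel_alignment: bool = True
    min_perfect_support: int = 4
    max_strand_fraction: float = 0.90

    def __post_init__(self) -> None:
        if min(
            self.min_map_quality,
            self.min_alt_base_quality,
            self.min_flank_quality,
            self.max_mismatches,
            self.min_perfect_support,
        ) < 0:
            raise ValueError("perfect-read parameters must be non-negative")


def is_perfect_read(obs: ReadObservation, params: PerfectReadParams = PerfectReadParams()) -> bool:
    """True iff the observation's read meets every perfect-read criterion."""
    if obs.map_quality < params.min_map_quality:
        return False
    if obs.base_quality < params.min_alt_base_quality:
        return False
    if any(q < params.min_flank_quality for q in obs.flank_qualities):
        return False
    if params.require_proper_pair and not obs.properly_paired:
        return False
    if obs.mismatch_count >= params.max_mismatches:
        return False
    if params.forbid_indel_alignment and obs.has_indel_alignment:
        return False
    return True


def _role_support_verdict(
    call: VariantCall,
    column: PileupColumn,
    role: SampleRole,
    params: PerfectReadParams,
) -> FilterVerdict:
    observations = column.role_observations(role)
    perfect = [
        o for o in observations if o.base in (call.ref, call.alt) and is_perfect_read(o, params)
    ]
    perfect_alt = [o for o in perfect if o.base == call.alt]
    failed: list[str] = []
    if len(perfect_alt) < params.min_perfect_support:
        failed.append("perfect_support")
    elif perfect:
        forward = sum(1 for o in perfect if o.strand is Strand.FORWARD)
        skew = max(forward, len(perfect) - forward) / len(perfect)
        if skew > params.max_strand_fraction:
            failed.append("perfect_strand_bias")
    return FilterVerdict(tuple(failed))


#: Which sample carries the evidence the perfect-read filter inspects.
_SUPPORT_ROLES: dict[str, tuple[SampleRole, ...]] = {
    "DNA_only": (SampleRole.TUMOR_DNA,),
    "RNA_Rescue": (SampleRole.TUMOR_RNA,),
    "RNA_Confirmation": (SampleRole.TUMOR_DNA, SampleRole.TUMOR_RNA),
}


def read_support_filter(
    call: VariantCall,
    column: PileupColumn,
    params: PerfectReadParams = PerfectReadParams(),
) -> FilterVerdict:
    """Final perfect-read support check for one merged somatic call.

    The inspected sample follows the call's evidence source: tumor DNA for
    DNA-only calls, tumor RNA for rescued calls; a call confirmed by both
    paths passes when either sample passes.
    """
    roles = _SUPPORT_ROLES.get(call.label or "DNA_only", (SampleRole.TUMOR_DNA,))
    verdicts = [_role_support_verdict(call, column, role, params) for role in roles]
    if any(v.passed for v in verdicts):
        return FilterVerdict()
    # de-duplicate names across roles, preserving order
    names: list[str] = []
    for v in verdicts:
        for name in v.failed_filters:
            if name not in names:
                names.append(name)
    return FilterVerdict(tuple(names))


def merge_calls(
    dom_calls: Sequence[VariantCall], tbm_calls: Sequence[VariantCall]
) -> list[VariantCall]:
    """Merge passing somatic calls from the two paths and label them.

    Same-site same-allele pairs collapse into one call with origin
    ``both`` / label ``RNA_Confirmation``; path-exclusive calls become
    ``DNA_only`` or ``RNA_Rescue``.  Germline calls pass through unlabeled.
    A same-site different-allele pair is kept as two records and logged.
    Output is sorted by (chrom, pos, alt); the operation is idempotent and
    does not depend on input order.
    """
    merged: list[VariantCall] = []
    tbm_by_key = {(c.chrom, c.pos, c.alt): c for c in tbm_calls if c.category == "somatic"}
    tbm_sites = {(c.chrom, c.pos) for c in tbm_calls if c.category == "somatic"}
    used: set[tuple[str, int, str]] = set()

    for call in dom_calls:
        if call.category != "somatic":
            merged.append(call)
            continue
        key = (call.chrom, call.pos, call.alt)
        partner = tbm_by_key.get(key)
        if partner is not None:
            used.add(key)
            summaries = dict(call.summaries)
            summaries.update(partner.summaries)
            merged.append(
                VariantCall(
                    chrom=call.chrom,
                    pos=call.pos,
                    ref=call.ref,
                    alt=call.alt,
                    category="somatic",
                    origin="both",
                    label="RNA_Confirmation",
                    summaries=summaries,
                    verdicts=list(call.verdicts) + list(partner.verdicts),
                )
            )
        else:
            if (call.chrom, call.pos) in tbm_sites:
                logger.warning(
                    "conflicting alt alleles at %s:%d; keeping both calls",
                    call.chrom,
                    call.pos + 1,
                )
            call.label = "DNA_only"
            merged.append(call)

    for call in tbm_calls:
        if call.category != "somatic":
            merged.append(call)
            continue
        if (call.chrom, call.pos, call.alt) in used:
            continue
        call.label = "RNA_Rescue"
        merged.append(call)

    merged.sort(key=lambda c: (c.chrom, c.pos, c.alt, c.category))
    return merged


def format_vaf_percent(alt_depth: int, depth: int) -> int:
    """Integer variant-allele-frequency percentage, rounded half away from
    zero (20/40 → 50, 31/34 → 91)."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    if alt_depth < 0:
        raise ValueError("alt_depth must be non-negative")
    pct = Fraction(100 * alt_depth, depth)
    whole, frac = divmod(pct, 1)
    return int(whole) + (1 if frac >= Fraction(1, 2) else 0)


# ---------------------------------------------------------------------------
# VCF output
# ---------------------------------------------------------------------------

_FILTER_DESCRIPTIONS = {
    "blacklist": "Site in the accessible-genome blacklist",
    "dbsnp_common": "Site overlaps a common known polymorphism",
    "dbsnp_retired": "Site overlaps a position retired from later dbSNP versions",
    "pseudogene": "Site overlaps an annotated or predicted pseudogene",
    "gene_family": "Site in a high-sequence-similarity gene family",
    "positional_bias": ">=95% of alt reads carry the allele in the first or last third of the read",
    "remap_min_valid_reads": "Fewer than 4 alt reads remap best to this locus",
    "remap_min_fraction": "Remapped alt reads below 10% of total depth",
    "perfect_support": "Fewer than 4 perfect reads support the mutation",
    "perfect_strand_bias": ">90% of perfect reads on one strand",
}

_SAMPLE_ORDER = (SampleRole.NORMAL_DNA, SampleRole.TUMOR_DNA, SampleRole.TUMOR_RNA)
DEFAULT_SAMPLE_NAMES = {
    SampleRole.NORMAL_DNA: "NORMAL_DNA",
    SampleRole.TUMOR_DNA: "TUMOR_DNA",
    SampleRole.TUMOR_RNA: "TUMOR_RNA",
}


def _format_sample(call: VariantCall, role: SampleRole) -> str:
    summary = call.summaries[role]
    other = round(summary.other_fraction * summary.depth)
    ref_depth = summary.depth - summary.alt_depth - other
    af = f"{summary.alt_fraction:.4f}"
    bq = "." if summary.avg_alt_base_quality is None else f"{summary.avg_alt_base_quality:.1f}"
    mq = "." if summary.avg_map_quality is None else f"{summary.avg_map_quality:.1f}"
    return f"{summary.depth}:{ref_depth},{summary.alt_depth}:{af}:{bq}:{mq}"


def write_vcf(
    calls: Sequence[VariantCall],
    sample_names: Mapping[SampleRole, str] = DEFAULT_SAMPLE_NAMES,
    out: str | Path | IO[str] | None = None,
) -> str:
    """Render calls as a VCF 4.2 document (returned; also written to ``out``
    when given).  Positions are 1-based in the output; rendering is
    deterministic, so identical call lists give byte-identical files."""
    lines = ["##fileformat=VCFv4.2", "##source=triplecall"]
    for chrom in sorted({c.chrom for c in calls}):
        lines.append(f"##contig=<ID={chrom}>")
    seen_filters = sorted({name for c in calls for name in c.failed_filters})
    for name in seen_filters:
        desc = _FILTER_DESCRIPTIONS.get(name, "Threshold filter " + name)
        lines.append(f'##FILTER=<ID={name},Description="{desc}">')
    lines += [
        '##INFO=<ID=SS,Number=1,Type=String,Description="Variant category: germline or somatic">',
        '##INFO=<ID=ORIGIN,Number=1,Type=String,Description="Calling path: DOM, TBM or both">',
        '##INFO=<ID=LABEL,Number=1,Type=String,Description="Somatic class: RNA_Confirmation, RNA_Rescue or DNA_only">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype (unphased, heuristic)">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Quality-filtered read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Reference and alt allele depths">',
        '##FORMAT=<ID=AF,Number=1,Type=Float,Description="Alt allele fraction">',
        '##FORMAT=<ID=BQ,Number=1,Type=Float,Description="Average alt base quality (phred)">',
        '##FORMAT=<ID=MQ,Number=1,Type=Float,Description="Average mapping quality (phred)">',
    ]
    header_cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    header_cols += [sample_names[r] for r in _SAMPLE_ORDER]
    lines.append("\t".join(header_cols))

    for call in sorted(calls, key=lambda c: (c.chrom, c.pos, c.alt, c.category)):
        info = f"SS={call.category};ORIGIN={call.origin}"
        if call.label:
            info += f";LABEL={call.label}"
        fields = [
            call.chrom,
            str(call.pos + 1),
            ".",
            call.ref,
            call.alt,
            ".",
            call.filter_field,
            info,
            "GT:DP:AD:AF:BQ:MQ",
        ]
        for role in _SAMPLE_ORDER:
            fields.append(_format_gt_sample(call, role))
        lines.append("\t".join(fields))

    text = "\n".join(lines) + "\n"
    if out is not None:
        if hasattr(out, "write"):
            out.write(text)  # type: ignore[union-attr]
        else:
            Path(out).write_text(text)
    return text


def _format_gt_sample(call: VariantCall, role: SampleRole) -> str:
    summary = call.summaries.get(role)
    if summary is None or summary.depth == 0:
        return "./.:.:.,.:.:.:."
    gt = "0/1" if summary.alt_depth > 0 else "0/0"
    return f"{gt}:{_format_sample(call, role)}"


def filter_report(rejected: Iterable[VariantCall]) -> dict[str, Counter]:
    """Tally rejected candidates per calling path, attributing each to its
    *first* failed filter (so the per-path totals reconcile with
    candidates − emitted calls)."""
    report: dict[str, Counter] = {}
    for call in rejected:
        failed = call.failed_filters
        if not failed:
            continue
        report.setdefault(call.origin, Counter())[failed[0]] += 1
    return report
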
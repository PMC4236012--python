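"""Per-call statistical filters.

Four families of checks remove false positives from lenient candidates:

* **Pileup-support threshold sets** — named bundles of minimum/maximum
  cuts on depth, alt depth, alt fraction, average alt base quality, strand
  balance of alt reads, and the fraction of reads supporting a third
  allele.  An absent field is simply not enforced, so one mechanism covers
  every column of the published threshold tables.
* **Strand bias** — variant reads sitting almost exclusively on one
  sequencing strand are an artifact signature.  With at least four
  alt-supporting reads, the site fails when more than 90% of them lie on
  one strand (either strand; the check is symmetric).
* **Positional bias** — misaligned reads tend to carry the alternative
  allele near a read end.  The site fails when 95% or more of the
  alt-supporting reads place the allele in the first or the last third of
  the read.
* **Remap check** — each variant-supporting read (typically RNA-seq, where
  splice junctions and paralogs confound mapping) is re-aligned against
  candidate regions; a read whose best placement is strictly elsewhere is
  dropped, after which at least four surviving reads and 10% support of the
  total depth are required.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence

from .read_model import AlleleSummary, ReadObservation

__all__ = [
    "ThresholdSet",
    "FilterVerdict",
    "apply_thresholds",
    "strand_bias_filter",
    "positional_bias_filter",
    "remap_check",
    "RemapAligner",
    "Placement",
    "RegionRemapAligner",
]

logger = logging.getLogger(__name__)

#: Strand bias is only assessed once this many reads support the variant.
STRAND_BIAS_MIN_ALT_DEPTH = 4
STRAND_BIAS_MAX_FRACTION = 0.90
POSITIONAL_BIAS_THRESHOLD = 0.95


@dataclass(frozen=True)
class FilterVerdict:
    """Outcome of one or more filters; ``passed`` iff no filter failed."""

    failed_filters: tuple[str, ...] = ()

    @property
    def passed(self) -> bool:
        return not self.failed_filters

    def __and__(self, other: "FilterVerdict") -> "FilterVerdict":
        return FilterVerdict(self.failed_filters + other.failed_filters)


PASS = FilterVerdict()


@dataclass(frozen=True)
class ThresholdSet:
    """One column of a pileup-support filter table.

    ``None`` means the cut is not enforced.  ``min_*`` cuts pass at >=,
    ``max_*`` cuts pass at <=.  The strand cut compares
    ``max(f, 1 - f)`` of the alt forward fraction ``f`` and, like the
    standalone strand-bias filter, only engages once at least
    ``strand_bias_min_alt_depth`` reads support the variant.
    """

    name: str = "thresholds"
    min_total_depth: int | None = None
    min_alt_depth: int | None = None
    min_alt_fraction: float | None = None
    min_avg_alt_base_quality: float | None = None
    max_alt_strand_fraction: float | None = None
    max_alt_fraction: float | None = None
    max_other_fraction: float | None = None
    strand_bias_min_alt_depth: int = STRAND_BIAS_MIN_ALT_DEPTH

    def __post_init__(self) -> None:
        for frac in (
            self.min_alt_fraction,
            self.max_alt_strand_fraction,
            self.max_alt_fraction,
            self.max_other_fraction,
        ):
            if frac is not None and not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction threshold {frac} outside [0, 1]")


def apply_thresholds(summary: AlleleSummary, thresholds: ThresholdSet) -> FilterVerdict:
    """Check every present cut of ``thresholds`` against ``summary``.

    Failed filter names are reported as ``<set name>.<cut>`` so that a
    rejection report can attribute failures to a sample role.
    """
    t = thresholds
    failed: list[str] = []

    def fail(cut: str) -> None:
        failed.append(f"{t.name}.{cut}")

    if t.min_total_depth is not None and summary.depth < t.min_total_depth:
        fail("min_total_depth")
    if t.min_alt_depth is not None and summary.alt_depth < t.min_alt_depth:
        fail("min_alt_depth")
    if t.min_alt_fraction is not None and summary.alt_fraction < t.min_alt_fraction:
        fail("min_alt_fraction")
    if t.min_avg_alt_base_quality is not None and (
        summary.avg_alt_base_quality is None
        or summary.avg_alt_base_quality < t.min_avg_alt_base_quality
    ):
        fail("min_avg_alt_base_quality")
    if (
        t.max_alt_strand_fraction is not None
        and summary.alt_depth >= t.strand_bias_min_alt_depth
        and summary.alt_forward_fraction is not None
    ):
        skew = max(summary.alt_forward_fraction, 1.0 - summary.alt_forward_fraction)
        if skew > t.max_alt_strand_fraction:
            fail("strand_bias")
    if t.max_alt_fraction is not None and summary.alt_fraction > t.max_alt_fraction:
        fail("max_alt_fraction")
    if t.max_other_fraction is not None and summary.other_fraction > t.max_other_fraction:
        fail("max_other_fraction")
    return FilterVerdict(tuple(failed))


def strand_bias_filter(
    summary: AlleleSummary,
    min_alt_for_bias: int = STRAND_BIAS_MIN_ALT_DEPTH,
    max_fraction: float = STRAND_BIAS_MAX_FRACTION,
) -> FilterVerdict:
    """Fail when >= ``min_alt_for_bias`` reads support the variant and more
    than ``max_fraction`` of them lie on one strand."""
    if summary.alt_depth < min_alt_for_bias or summary.alt_forward_fraction is None:
        return PASS
    skew = max(summary.alt_forward_fraction, 1.0 - summary.alt_forward_fraction)
    if skew > max_fraction:
        return FilterVerdict(("strand_bias",))
    return PASS


def positional_bias_filter(
    alt_observations: Sequence[ReadObservation],
    threshold: float = POSITIONAL_BIAS_THRESHOLD,
) -> FilterVerdict:
    """Fail when ``threshold`` (default 95%) or more of the alt-supporting
    reads carry the allele in the first third or in the last third of the
    read.  Thirds are real-valued: offset/length < 1/3 or >= 2/3."""
    if not alt_observations:
        return PASS
    n = len(alt_observations)
    start = sum(1 for o in alt_observations if o.relative_position < 1 / 3)
    end = sum(1 for o in alt_observations if o.relative_position >= 2 / 3)
    if start / n >= threshold or end / n >= threshold:
        return FilterVerdict(("positional_bias",))
    return PASS


# ---------------------------------------------------------------------------
# Remap (re-alignment) check
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Placement:
    """One scored placement of a read on the genome."""

    chrom: str
    start: int
    end: int  # half-open
    score: float

    def overlaps(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


class RemapAligner(Protocol):
    """Contract for the remap check: given a read sequence, return its
    best-scoring placement(s) genome-wide."""

    def best_placements(self, sequence: str) -> list[Placement]: ...


class RegionRemapAligner:
    """Self-contained default aligner: exhaustive local alignment of the
    read against every sequence of a candidate-region FASTA (the locus
    neighborhood plus any declared homologs).

    Record names of the form ``chrom:start`` (0-based offset) anchor a
    region on the genome; a bare name is taken as a whole contig at offset
    0.  An adapter shelling out to an external genome-wide aligner can be
    swapped in anywhere a :class:`RemapAligner` is accepted.
    """

    _NAME_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)(?:-\d+)?$")

    def __init__(self, fasta_path: str | Path | None = None, regions: dict[str, str] | None = None):
        from Bio import SeqIO
        from Bio.Align import PairwiseAligner

        self._regions: list[tuple[str, int, str]] = []  # (chrom, offset, seq)
        named: dict[str, str] = dict(regions or {})
        if fasta_path is not None:
            for rec in SeqIO.parse(str(fasta_path), "fasta"):
                named[rec.id] = str(rec.seq).upper()
        for name, seq in named.items():
            match = self._NAME_RE.match(name)
            if match:
                self._regions.append((match["chrom"], int(match["start"]), seq.upper()))
            else:
                self._regions.append((name, 0, seq.upper()))
        self._aligner = PairwiseAligner(
            mode="local",
            match_score=1,
            mismatch_score=-1,
            open_gap_score=-2,
            extend_gap_score=-1,
        )

    def best_placements(self, sequence: str) -> list[Placement]:
        best: list[Placement] = []
        best_score: float | None = None
        for chrom, offset, region_seq in self._regions:
            alns = self._aligner.align(region_seq, sequence.upper())
            if len(alns) == 0:
                continue
            aln = alns[0]
            score = float(aln.score)
            start = int(aln.aligned[0][0][0]) + offset
            end = int(aln.aligned[0][-1][1]) + offset
            placement = Placement(chrom=chrom, start=start, end=end, score=score)
            if best_score is None or score > best_score:
                best, best_score = [placement], score
            elif score == best_score:
                best.append(placement)
        return best


def remap_check(
    alt_observations: Sequence[ReadObservation],
    chrom: str,
    pos: int,
    aligner: RemapAligner,
    total_depth: int,
    min_valid_reads: int = 4,
    min_fraction: float = 0.10,
) -> FilterVerdict:
    """Re-align every variant-supporting read and re-assess support.

    A read survives when some best-scoring placement overlaps the call
    locus (a strictly better score elsewhere rejects it; a read without a
    stored sequence is rejected with a warning).  The site fails when fewer
    than ``min_valid_reads`` reads survive or the survivors make up less
    than ``min_fraction`` of ``total_depth``.
    """
    surviving = 0
    for obs in alt_observations:
        if obs.read_sequence is None:
            logger.warning(
                "read %s has no stored sequence; counted as rejected by remap check",
                obs.read_id,
            )
            continue
        placements = aligner.best_placements(obs.read_sequence)
        if any(p.overlaps(chrom, pos) for p in placements):
            surviving += 1
    failed: list[str] = []
    if surviving < min_valid_reads:
        failed.append("remap_min_valid_reads")
    if total_depth > 0 and surviving / total_depth < min_fraction:
        failed.append("remap_min_fraction")
    return FilterVerdict(tuple(failed))
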
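"""Domain model for per-position read observations.

A *pileup column* collects, for one genomic position, every aligned read
base from up to three patient-matched samples: normal DNA, tumor DNA and
tumor RNA.  Each observation carries the per-read quantities the downstream
filters consume: base and mapping quality, strand, the base's offset within
the read, pairing state, the read's genome-wide mismatch count, whether the
alignment required an insertion or deletion, and the qualities of the five
flanking bases on either side.

Two input routes produce columns: a pileup traversal over coordinate-sorted
indexed BAM files (via pysam), and a plain-text one-observation-per-row TSV
dialect intended for small, fully inspectable datasets.

Coordinates are 0-based internally; VCF output is 1-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence

__all__ = [
    "SampleRole",
    "Strand",
    "ReadObservation",
    "PileupColumn",
    "AlleleSummary",
    "PileupParseError",
    "summarize_column",
    "read_pileup_tsv",
    "write_pileup_tsv",
    "read_bam_pileup",
    "PILEUP_TSV_COLUMNS",
]

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
#: Deterministic alt-allele tie-break order.
BASE_ORDER = "ACGT"


class SampleRole(str, Enum):
    """The three sample roles of a patient triplet."""

    NORMAL_DNA = "normal_dna"
    TUMOR_DNA = "tumor_dna"
    TUMOR_RNA = "tumor_rna"


class Strand(str, Enum):
    FORWARD = "+"
    REVERSE = "-"


@dataclass(frozen=True)
class ReadObservation:
    """One aligned base at one genomic position.

    ``flank_qualities`` holds the qualities of up to five bases upstream and
    five downstream of this base *within the read* (fewer near read ends).
    ``mismatch_count`` is the whole read's mismatch count versus the
    reference, excluding inserted/deleted bases.  ``read_sequence`` is only
    required by the remap (re-alignment) check and may be ``None``.
    """

    read_id: str
    base: str
    base_quality: int
    map_quality: int
    strand: Strand
    offset_in_read: int
    read_length: int
    properly_paired: bool
    mismatch_count: int
    has_indel_alignment: bool
    flank_qualities: tuple[int, ...] = ()
    sample_role: SampleRole = SampleRole.TUMOR_DNA
    read_sequence: str | None = None

    def __post_init__(self) -> None:
        if self.base not in VALID_BASES:
            raise ValueError(f"invalid base {self.base!r}")
        if not 0 <= self.offset_in_read < self.read_length:
            raise ValueError(
                f"offset {self.offset_in_read} outside read of length {self.read_length}"
            )
        if len(self.flank_qualities) > 10:
            raise ValueError("at most 10 flank qualities (5 up- + 5 downstream)")
        if self.base_quality < 0 or self.map_quality < 0:
            raise ValueError("phred qualities must be non-negative")
        if self.mismatch_count < 0:
            raise ValueError("mismatch_count must be non-negative")

    @property
    def relative_position(self) -> float:
        """Offset as a fraction of read length, in [0, 1)."""
        return self.offset_in_read / self.read_length


@dataclass
class PileupColumn:
    """All observations at one 0-based genomic position, keyed by role."""

    chrom: str
    pos: int
    ref_base: str
    observations: dict[SampleRole, list[ReadObservation]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ref_base = self.ref_base.upper()
        if self.ref_base not in VALID_BASES:
            raise ValueError(f"invalid reference base {self.ref_base!r}")
        for role, obs_list in self.observations.items():
            for obs in obs_list:
                if obs.sample_role != role:
                    raise ValueError(
                        f"observation with role {obs.sample_role} filed under {role}"
                    )

    def role_observations(self, role: SampleRole) -> list[ReadObservation]:
        return self.observations.get(role, [])


@dataclass(frozen=True)
class AlleleSummary:
    """Per-sample aggregate statistics for one alternative allele.

    ``alt_forward_fraction`` is ``None`` when no alt-supporting read passed
    the quality cuts; ``other_fraction`` is the fraction of counted reads
    supporting any base other than the reference and the alt allele.
    """

    depth: int
    alt_allele: str | None
    alt_depth: int
    alt_fraction: float
    avg_alt_base_quality: float | None
    avg_map_quality: float | None
    alt_forward_fraction: float | None
    other_fraction: float

    def __post_init__(self) -> None:
        if self.alt_depth > self.depth:
            raise ValueError("alt_depth exceeds depth")


def summarize_column(
    observations: Sequence[ReadObservation],
    ref_base: str,
    min_base_quality: int = 0,
    min_map_quality: int = 0,
    alt_allele: str | None = None,
) -> AlleleSummary:
    """Aggregate one role's observations into an :class:`AlleleSummary`.

    Observations below either quality cut, and ``N`` bases, are excluded
    from the depth and every fraction.  When ``alt_allele`` is ``None`` the
    alternative allele is the non-reference base with the highest surviving
    count (ties broken A<C<G<T); passing an explicit ``alt_allele`` forces
    the summary onto that base, which the triple-sample caller uses to ask
    e.g. "how many reads support the RNA's allele in the tumor DNA?".
    """
    ref_base = ref_base.upper()
    kept = [
        o
        for o in observations
        if o.base != "N"
        and o.base_quality >= min_base_quality
        and o.map_quality >= min_map_quality
    ]
    depth = len(kept)
    counts = {b: 0 for b in BASE_ORDER}
    for o in kept:
        counts[o.base] += 1

    if alt_allele is None:
        best = None
        for b in BASE_ORDER:  # fixed order makes the tie-break lexicographic
            if b == ref_base:
                continue
            if counts[b] > 0 and (best is None or counts[b] > counts[best]):
                best = b
        alt_allele = best
    else:
        alt_allele = alt_allele.upper()
        if alt_allele not in BASE_ORDER:
            raise ValueError(f"invalid alt allele {alt_allele!r}")

    alt_obs = [o for o in kept if alt_allele is not None and o.base == alt_allele]
    alt_depth = len(alt_obs)
    alt_fraction = alt_depth / depth if depth else 0.0
    other = depth - counts.get(ref_base, 0) - alt_depth
    other_fraction = other / depth if depth else 0.0
    avg_alt_bq = (
        sum(o.base_quality for o in alt_obs) / alt_depth if alt_depth else None
    )
    avg_mq = sum(o.map_quality for o in kept) / depth if depth else None
    alt_fwd = (
        sum(1 for o in alt_obs if o.strand is Strand.FORWARD) / alt_depth
        if alt_depth
        else None
    )
    return AlleleSummary(
        depth=depth,
        alt_allele=alt_allele if alt_depth else (alt_allele or None),
        alt_depth=alt_depth,
        alt_fraction=alt_fraction,
        avg_alt_base_quality=avg_alt_bq,
        avg_map_quality=avg_mq,
        alt_forward_fraction=alt_fwd,
        other_fraction=other_fraction,
    )


# ---------------------------------------------------------------------------
# Plain-text pileup dialect
# ---------------------------------------------------------------------------

PILEUP_TSV_COLUMNS = (
    "chrom",
    "pos0",
    "refBase",
    "sampleRole",
    "readId",
    "base",
    "baseQual",
    "mapQual",
    "strand",
    "offsetInRead",
    "readLength",
    "properlyPaired",
    "mismatchCount",
    "hasIndel",
    "flankQuals",
    "readSeq",
)


class PileupParseError(ValueError):
    """Malformed pileup TSV; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


def _parse_row(fields: list[str], line_number: int) -> tuple[str, int, str, ReadObservation]:
    if len(fields) != len(PILEUP_TSV_COLUMNS):
        raise PileupParseError(
            f"expected {len(PILEUP_TSV_COLUMNS)} fields, got {len(fields)}", line_number
        )
    row = dict(zip(PILEUP_TSV_COLUMNS, fields))
    try:
        role = SampleRole(row["sampleRole"])
    except ValueError:
        raise PileupParseError(
            f"unknown sampleRole {row['sampleRole']!r}", line_number
        ) from None
    try:
        strand = Strand(row["strand"])
    except ValueError:
        raise PileupParseError(f"unknown strand {row['strand']!r}", line_number) from None
    flank = row["flankQuals"]
    try:
        flank_quals = tuple(int(q) for q in flank.split(",")) if flank not in ("", ".") else ()
        obs = ReadObservation(
            read_id=row["readId"],
            base=row["base"].upper(),
            base_quality=int(row["baseQual"]),
            map_quality=int(row["mapQual"]),
            strand=strand,
            offset_in_read=int(row["offsetInRead"]),
            read_length=int(row["readLength"]),
            properly_paired=row["properlyPaired"] == "1",
            mismatch_count=int(row["mismatchCount"]),
            has_indel_alignment=row["hasIndel"] == "1",
            flank_qualities=flank_quals,
            sample_role=role,
            read_sequence=None if row["readSeq"] in (".", "") else row["readSeq"].upper(),
        )
        pos = int(row["pos0"])
    except (ValueError, TypeError) as exc:
        raise PileupParseError(str(exc), line_number) from None
    return row["chrom"], pos, row["refBase"].upper(), obs


def read_pileup_tsv(path: str | Path) -> Iterator[PileupColumn]:
    """Stream :class:`PileupColumn` objects from the one-row-per-observation
    TSV dialect (header required; consecutive rows for one (chrom, pos) are
    grouped into a single column, in file order)."""
    current: PileupColumn | None = None
    with open(path) as handle:
        header = handle.readline()
        if header == "":
            return
        head_fields = header.rstrip("\n").split("\t")
        if head_fields != list(PILEUP_TSV_COLUMNS):
            raise PileupParseError(
                f"bad header: expected columns {', '.join(PILEUP_TSV_COLUMNS)}", 1
            )
        for line_number, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            chrom, pos, ref, obs = _parse_row(line.split("\t"), line_number)
            if current is None or (current.chrom, current.pos) != (chrom, pos):
                if current is not None:
                    yield current
                current = PileupColumn(chrom=chrom, pos=pos, ref_base=ref)
            current.observations.setdefault(obs.sample_role, []).append(obs)
    if current is not None:
        yield current


def write_pileup_tsv(columns: Iterable[PileupColumn], path_or_handle: str | Path | IO[str]) -> None:
    """Write columns in the TSV dialect (inverse of :func:`read_pileup_tsv`)."""

    def _write(handle: IO[str]) -> None:
        handle.write("\t".join(PILEUP_TSV_COLUMNS) + "\n")
        for col in columns:
            for role in SampleRole:
                for obs in col.role_observations(role):
                    handle.write(
                        "\t".join(
                            (
                                col.chrom,
                                str(col.pos),
                                col.ref_base,
                                role.value,
                                obs.read_id,
                                obs.base,
                                str(obs.base_quality),
                                str(obs.map_quality),
                                obs.strand.value,
                                str(obs.offset_in_read),
                                str(obs.read_length),
                                "1" if obs.properly_paired else "0",
                                str(obs.mismatch_count),
                                "1" if obs.has_indel_alignment else "0",
                                ",".join(str(q) for q in obs.flank_qualities),
                                obs.read_sequence or ".",
                            )
                        )
                        + "\n"
                    )

    if hasattr(path_or_handle, "write"):
        _write(path_or_handle)  # type: ignore[arg-type]
    else:
        with open(path_or_handle, "w") as handle:
            _write(handle)


# ---------------------------------------------------------------------------
# BAM pileup traversal
# ---------------------------------------------------------------------------


def _mismatch_count(read) -> int:
    """Mismatches of the whole read vs the reference: NM minus inserted and
    deleted bases; recomputed from MD when NM is absent; 0 with a warning
    when neither tag exists."""
    indel_bases = sum(
        length for op, length in (read.cigartuples or []) if op in (1, 2)  # I, D
    )
    if read.has_tag("NM"):
        return max(int(read.get_tag("NM")) - indel_bases, 0)
    if read.has_tag("MD"):
        import re

        md = str(read.get_tag("MD"))
        # Mismatched reference bases appear as single letters outside deletions.
        mismatches = len(re.findall(r"(?<!\^)[A-Z]", re.sub(r"\^[A-Z]+", "", md)))
        return mismatches
    logger.warning("read %s lacks NM and MD tags; mismatch count set to 0", read.query_name)
    return 0


def read_bam_pileup(
    bam_paths: Mapping[SampleRole, str | Path],
    reference: str | Path,
    region: tuple[str, int, int] | None = None,
    single_end_properly_paired: bool = True,
    min_base_quality: int = 0,
    min_map_quality: int = 0,
) -> Iterator[PileupColumn]:
    """Traverse coordinate-sorted indexed BAMs and yield merged columns.

    ``region`` is (chrom, start, end) 0-based half-open; required when the
    BAMs cover more than one contig.  Unpaired reads count as properly
    paired by default (single-end RNA libraries), controllable via
    ``single_end_properly_paired``.
    """
    import pysam

    fasta = pysam.FastaFile(str(reference))
    per_role: dict[SampleRole, dict[tuple[str, int], list[ReadObservation]]] = {}
    for role, path in bam_paths.items():
        columns: dict[tuple[str, int], list[ReadObservation]] = {}
        with pysam.AlignmentFile(str(path), "rb") as bam:
            kwargs = {}
            if region is not None:
                kwargs = {"contig": region[0], "start": region[1], "stop": region[2]}
            for pile in bam.pileup(
                min_base_quality=min_base_quality,
                min_mapping_quality=min_map_quality,
                ignore_overlaps=False,
                stepper="nofilter",
                truncate=region is not None,
                **kwargs,
            ):
                obs_list = []
                for pread in pile.pileups:
                    if pread.is_del or pread.is_refskip or pread.query_position is None:
                        continue
                    read = pread.alignment
                    qpos = pread.query_position
                    quals = read.query_qualities
                    seq = read.query_sequence
                    if seq is None or quals is None:
                        continue
                    base = seq[qpos].upper()
                    if base not in VALID_BASES:
                        base = "N"
                    flank = tuple(
                        quals[i]
                        for i in range(max(0, qpos - 5), min(len(quals), qpos + 6))
                        if i != qpos
                    )
                    paired = read.is_proper_pair
                    if not read.is_paired and single_end_properly_paired:
                        paired = True
                    obs_list.append(
                        ReadObservation(
                            read_id=read.query_name,
                            base=base,
                            base_quality=int(quals[qpos]),
                            map_quality=int(read.mapping_quality),
                            strand=Strand.REVERSE if read.is_reverse else Strand.FORWARD,
                            offset_in_read=int(qpos),
                            read_length=len(seq),
                            properly_paired=paired,
                            mismatch_count=_mismatch_count(read),
                            has_indel_alignment=any(
                                op in (1, 2) for op, _ in (read.cigartuples or [])
                            ),
                            flank_qualities=flank,
                            sample_role=role,
                            read_sequence=seq.upper(),
                        )
                    )
                if obs_list:
                    columns[(pile.reference_name, pile.reference_pos)] = obs_list
        per_role[role] = columns

    all_keys = sorted({k for cols in per_role.values() for k in cols})
    for chrom, pos in all_keys:
        ref = fasta.fetch(chrom, pos, pos + 1).upper()
        if ref not in VALID_BASES:
            ref = "N"
        yield PileupColumn(
            chrom=chrom,
            pos=pos,
            ref_base=ref,
            observations={
                role: cols[(chrom, pos)]
                for role, cols in per_role.items()
                if (chrom, pos) in cols
            },
        )


def flip_strand(obs: ReadObservation) -> ReadObservation:
    """Return the observation with its strand reversed (used in tests and in
    symmetry checks of the strand-bias filter)."""
    return replace(
        obs,
        strand=Strand.REVERSE if obs.strand is Strand.FORWARD else Strand.FORWARD,
    )
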
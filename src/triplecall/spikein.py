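"""Read-level mutation spike-in for benchmarking.

To measure sensitivity without a known truth set, artificial somatic
mutations are written directly into the reads of existing tumor DNA and
tumor RNA pileups: eligible loci (sufficient depth in both samples,
reference-homozygous in every sample) are chosen, a target variant allele
frequency is drawn per locus from a configurable distribution, and
``round(VAF × depth)`` reads have their base at the locus changed to the
alternative allele, preserving base qualities.  Because real reads are
edited in place, the simulated data keeps the depth, quality and strand
structure of the source data.  A truth table records every edit, including
the achieved VAF (which differs from the target only by rounding:
|achieved − target| <= 1/(2·depth)).

Editing happens at the pileup-column level without re-mapping; when
operating on real alignments a re-mapping hook can be applied downstream.
All randomness flows from the spec's seed, so a spike-in run is fully
reproducible.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Callable, Iterable, Iterator, Sequence

from .read_model import PileupColumn, SampleRole

__all__ = [
    "VafSampler",
    "SpikeInSpec",
    "TruthRecord",
    "select_loci",
    "spike_mutation",
    "spike_dataset",
    "write_truth",
    "read_truth",
    "TRUTH_COLUMNS",
]

logger = logging.getLogger(__name__)

BASES = "ACGT"


@dataclass(frozen=True)
class VafSampler:
    """A distribution descriptor for target variant allele frequencies."""

    draw: Callable[[random.Random], float]
    description: str = "custom"

    @classmethod
    def constant(cls, value: float) -> "VafSampler":
        if not 0.0 <= value <= 1.0:
            raise ValueError("VAF must lie in [0, 1]")
        return cls(lambda rng: value, f"constant:{value}")

    @classmethod
    def uniform(cls, low: float, high: float) -> "VafSampler":
        if not 0.0 <= low <= high <= 1.0:
            raise ValueError("VAF range must lie in [0, 1]")
        return cls(lambda rng: rng.uniform(low, high), f"uniform:{low}-{high}")

    @classmethod
    def parse(cls, text: str) -> "VafSampler":
        """Parse ``constant:0.25`` or ``uniform:0.01-0.5``."""
        kind, _, arg = text.partition(":")
        if kind == "constant":
            return cls.constant(float(arg))
        if kind == "uniform":
            low, _, high = arg.partition("-")
            return cls.uniform(float(low), float(high))
        raise ValueError(f"unknown VAF sampler {text!r}")

    def sample(self, rng: random.Random) -> float:
        value = self.draw(rng)
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"sampled VAF {value} outside [0, 1]")
        return value


@dataclass
class SpikeInSpec:
    """Conditions of one spike-in experiment."""

    dna_vaf_sampler: VafSampler = field(default_factory=lambda: VafSampler.uniform(0.01, 0.50))
    rna_vaf_sampler: VafSampler = field(default_factory=lambda: VafSampler.constant(0.25))
    min_dna_depth: int = 10
    min_rna_depth: int = 10
    seed: int = 0


@dataclass(frozen=True)
class TruthRecord:
    """One spiked mutation in one sample role."""

    chrom: str
    pos: int  # 0-based internal
    ref: str
    alt: str
    role: SampleRole
    target_vaf: float
    achieved_vaf: float
    read_ids: tuple[str, ...]


def _reference_homozygous(column: PileupColumn) -> bool:
    return all(
        obs.base in (column.ref_base, "N")
        for obs_list in column.observations.values()
        for obs in obs_list
    )


def select_loci(
    columns: Iterable[PileupColumn],
    spec: SpikeInSpec,
    n: int,
    rng: random.Random | None = None,
) -> list[PileupColumn]:
    """Choose ``n`` eligible columns for spiking, uniformly at random.

    Eligible: tumor-DNA depth >= ``min_dna_depth``, tumor-RNA depth >=
    ``min_rna_depth``, and reference-homozygous in every sample role.
    Fewer than ``n`` eligible loci returns all of them with a warning.
    """
    rng = rng or random.Random(spec.seed)
    eligible = [
        col
        for col in columns
        if len(col.role_observations(SampleRole.TUMOR_DNA)) >= spec.min_dna_depth
        and len(col.role_observations(SampleRole.TUMOR_RNA)) >= spec.min_rna_depth
        and _reference_homozygous(col)
    ]
    if len(eligible) <= n:
        if len(eligible) < n:
            logger.warning("only %d of %d requested loci are eligible", len(eligible), n)
        return eligible
    chosen = rng.sample(range(len(eligible)), n)
    return [eligible[i] for i in sorted(chosen)]


def _round_half_away(x: float) -> int:
    return int(x + 0.5) if x >= 0 else -int(-x + 0.5)


def spike_mutation(
    column: PileupColumn,
    role: SampleRole,
    alt: str,
    target_vaf: float,
    rng: random.Random,
) -> tuple[PileupColumn, TruthRecord | None]:
    """Edit ``round(target_vaf × depth)`` reads of ``role`` to carry ``alt``.

    Returns the modified column (a new object; the input is not mutated)
    and the truth record, or ``(column, None)`` when the rounded read count
    is zero — the mutation cannot be represented at this depth and the site
    is reported as skipped.
    """
    observations = column.role_observations(role)
    depth = len(observations)
    k = _round_half_away(target_vaf * depth)
    if k == 0:
        logger.info(
            "skipping %s:%d (%s): target VAF %.4f rounds to 0 of %d reads",
            column.chrom,
            column.pos + 1,
            role.value,
            target_vaf,
            depth,
        )
        return column, None
    editable = [i for i, o in enumerate(observations) if o.base == column.ref_base]
    if len(editable) < k:
        raise ValueError("not enough reference-supporting reads to spike")
    chosen = sorted(rng.sample(editable, k))
    new_obs = list(observations)
    for i in chosen:
        new_obs[i] = replace(observations[i], base=alt)
    new_column = PileupColumn(
        chrom=column.chrom,
        pos=column.pos,
        ref_base=column.ref_base,
        observations={**column.observations, role: new_obs},
    )
    record = TruthRecord(
        chrom=column.chrom,
        pos=column.pos,
        ref=column.ref_base,
        alt=alt,
        role=role,
        target_vaf=target_vaf,
        achieved_vaf=k / depth,
        read_ids=tuple(observations[i].read_id for i in chosen),
    )
    return new_column, record


def spike_dataset(
    columns: Iterable[PileupColumn],
    spec: SpikeInSpec,
    n: int,
) -> tuple[list[PileupColumn], list[TruthRecord]]:
    """Run a full spike-in experiment over a column stream.

    Selects ``n`` eligible loci, draws one DNA and one RNA target VAF per
    locus, and spikes the *same* randomly chosen alternative allele into
    the tumor DNA and tumor RNA.  Non-selected columns pass through
    untouched, in order.
    """
    rng = random.Random(spec.seed)
    columns = list(columns)
    selected = {(c.chrom, c.pos) for c in select_loci(columns, spec, n, rng)}
    out_columns: list[PileupColumn] = []
    records: list[TruthRecord] = []
    for column in columns:
        if (column.chrom, column.pos) not in selected:
            out_columns.append(column)
            continue
        alt = rng.choice([b for b in BASES if b != column.ref_base])
        dna_vaf = spec.dna_vaf_sampler.sample(rng)
        rna_vaf = spec.rna_vaf_sampler.sample(rng)
        column, dna_record = spike_mutation(
            column, SampleRole.TUMOR_DNA, alt, dna_vaf, rng
        )
        column, rna_record = spike_mutation(
            column, SampleRole.TUMOR_RNA, alt, rna_vaf, rng
        )
        out_columns.append(column)
        records.extend(r for r in (dna_record, rna_record) if r is not None)
    return out_columns, records


TRUTH_COLUMNS = (
    "chrom",
    "pos1",
    "ref",
    "alt",
    "role",
    "targetVaf",
    "achievedVaf",
    "readIds",
)


def write_truth(records: Sequence[TruthRecord], path_or_handle: str | Path | IO[str]) -> None:
    """Write the truth table as TSV (positions 1-based)."""

    def _write(handle: IO[str]) -> None:
        handle.write("\t".join(TRUTH_COLUMNS) + "\n")
        for r in records:
            handle.write(
                "\t".join(
                    (
                        r.chrom,
                        str(r.pos + 1),
                        r.ref,
                        r.alt,
                        r.role.value,
                        f"{r.target_vaf:.6f}",
                        f"{r.achieved_vaf:.6f}",
                        ",".join(r.read_ids),
                    )
                )
                + "\n"
            )

    if hasattr(path_or_handle, "write"):
        _write(path_or_handle)  # type: ignore[arg-type]
    else:
        with open(path_or_handle, "w") as handle:
            _write(handle)


def read_truth(path: str | Path) -> Iterator[TruthRecord]:
    """Parse a truth TSV back into records."""
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header != list(TRUTH_COLUMNS):
            raise ValueError(f"{path}: bad truth header")
        for line in handle:
            fields = line.rstrip("\n").split("\t")
            if not fields or fields == [""]:
                continue
            yield TruthRecord(
                chrom=fields[0],
                pos=int(fields[1]) - 1,
                ref=fields[2],
                alt=fields[3],
                role=SampleRole(fields[4]),
                target_vaf=float(fields[5]),
                achieved_vaf=float(fields[6]),
                read_ids=tuple(fields[7].split(",")) if fields[7] else (),
            )
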
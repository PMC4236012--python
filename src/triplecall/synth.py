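"""Synthetic triplet pileup generator.

Produces pileup columns for the three sample roles with controllable
depth, variant allele frequency, base/mapping quality, strand balance,
within-read position of the variant, mismatch load, pairing and
third-allele contamination — every knob the detection and filter stages
consume.  The generator emulates the *structure* of aligned sequencing
data, not any platform-specific error profile; its purpose is to make
every stage of the caller testable without external data.

The module also carries deliberately independent re-implementations of the
two calling decisions (:func:`independent_dom_expectation`,
:func:`independent_tbm_expectation`): straight-line translations of the
published threshold tables over raw observation lists, sharing no code
with the filter or calling modules.  The generated truth table records
their verdicts so caller output can be cross-checked against an oracle
that cannot fail in the same way the implementation would.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Callable, Sequence

from .read_model import (
    PileupColumn,
    ReadObservation,
    SampleRole,
    Strand,
    write_pileup_tsv,
)

__all__ = [
    "SynthColumnSpec",
    "generate_column",
    "generate_dataset",
    "random_spec",
    "independent_dom_expectation",
    "independent_tbm_expectation",
    "TRUTH_COLUMNS",
]

BASES = "ACGT"


def _round_half_away(x: float) -> int:
    return int(x + 0.5) if x >= 0 else -int(-x + 0.5)


@dataclass
class SynthColumnSpec:
    """Recipe for one synthetic pileup column.

    ``depth`` and ``true_vaf`` are per sample role; qualities are sampled
    from rounded, clipped normal distributions given as (mean, sd) pairs.
    ``strand_balance`` is the probability a read lies on the forward
    strand.  ``positional_bias`` places alt alleles in the first
    (``start``) or last (``end``) third of the read for a given fraction
    of alt reads.  ``other_allele_rate`` converts reference reads to a
    third allele (contamination), ``mismatch_mean`` drives a clipped
    exponential mismatch count per read.
    """

    chrom: str = "chr1"
    pos: int = 0
    ref_base: str = "G"
    alt_base: str = "T"
    depth: dict[SampleRole, int] = field(
        default_factory=lambda: {role: 30 for role in SampleRole}
    )
    true_vaf: dict[SampleRole, float] = field(
        default_factory=lambda: {
            SampleRole.NORMAL_DNA: 0.0,
            SampleRole.TUMOR_DNA: 0.3,
            SampleRole.TUMOR_RNA: 0.3,
        }
    )
    base_quality: tuple[float, float] = (35.0, 3.0)
    map_quality: tuple[float, float] = (60.0, 0.0)
    flank_quality: tuple[float, float] = (35.0, 3.0)
    strand_balance: float = 0.5
    positional_bias: str = "none"  # none | start | end
    positional_bias_fraction: float = 1.0
    mismatch_mean: float = 0.5
    proper_pair_rate: float = 1.0
    indel_rate: float = 0.0
    other_allele_rate: float = 0.0
    read_length: int = 100
    seed: int = 0


def _phred(rng: random.Random, dist: tuple[float, float], lo: int = 2, hi: int = 60) -> int:
    mean, sd = dist
    value = mean if sd == 0 else rng.gauss(mean, sd)
    return max(lo, min(hi, round(value)))


def _offset(rng: random.Random, spec: SynthColumnSpec, is_alt: bool) -> int:
    length = spec.read_length
    if is_alt and spec.positional_bias != "none" and rng.random() < spec.positional_bias_fraction:
        third = length // 3
        if spec.positional_bias == "start":
            return rng.randrange(0, max(third, 1))
        # last third: relative position >= 2/3
        lo = -(-2 * length // 3)  # ceil(2L/3)
        return rng.randrange(lo, length)
    return rng.randrange(0, length)


def generate_column(spec: SynthColumnSpec, rng: random.Random | None = None) -> PileupColumn:
    """Draw one column.  Alt read count per role is
    ``round(true_vaf × depth)`` exactly; everything else is sampled.
    Deterministic for a fixed seed."""
    rng = rng or random.Random(spec.seed)
    other_base = next(b for b in BASES if b not in (spec.ref_base, spec.alt_base))
    observations: dict[SampleRole, list[ReadObservation]] = {}
    for role in SampleRole:
        n = spec.depth.get(role, 0)
        if n == 0:
            continue
        k_alt = _round_half_away(spec.true_vaf.get(role, 0.0) * n)
        obs_list: list[ReadObservation] = []
        for i in range(n):
            is_alt = i < k_alt
            base = spec.alt_base if is_alt else spec.ref_base
            if not is_alt and rng.random() < spec.other_allele_rate:
                base = other_base
            mismatches = (
                min(int(rng.expovariate(1.0 / spec.mismatch_mean)), 10)
                if spec.mismatch_mean > 0
                else 0
            )
            obs_list.append(
                ReadObservation(
                    read_id=f"{role.value}_r{i}",
                    base=base,
                    base_quality=_phred(rng, spec.base_quality, hi=93),
                    map_quality=_phred(rng, spec.map_quality),
                    strand=(
                        Strand.FORWARD
                        if rng.random() < spec.strand_balance
                        else Strand.REVERSE
                    ),
                    offset_in_read=_offset(rng, spec, is_alt),
                    read_length=spec.read_length,
                    properly_paired=rng.random() < spec.proper_pair_rate,
                    mismatch_count=mismatches,
                    has_indel_alignment=rng.random() < spec.indel_rate,
                    flank_qualities=tuple(
                        _phred(rng, spec.flank_quality, hi=93) for _ in range(10)
                    ),
                    sample_role=role,
                )
            )
        observations[role] = obs_list
    return PileupColumn(
        chrom=spec.chrom, pos=spec.pos, ref_base=spec.ref_base, observations=observations
    )


def random_spec(rng: random.Random, pos: int = 0) -> SynthColumnSpec:
    """Sample a column recipe spanning the depth/VAF/quality grids the
    filter thresholds act on, including sub-threshold and biased corners."""
    ref = rng.choice(BASES)
    alt = rng.choice([b for b in BASES if b != ref])
    return SynthColumnSpec(
        pos=pos,
        ref_base=ref,
        alt_base=alt,
        depth={role: rng.randrange(0, 45) for role in SampleRole},
        true_vaf={
            SampleRole.NORMAL_DNA: rng.choice([0.0, 0.0, 0.01, 0.03, 0.1, 0.3, 0.5]),
            SampleRole.TUMOR_DNA: rng.choice([0.0, 0.02, 0.05, 0.09, 0.1, 0.12, 0.3, 0.5]),
            SampleRole.TUMOR_RNA: rng.choice([0.0, 0.02, 0.05, 0.09, 0.1, 0.12, 0.3, 0.5]),
        },
        base_quality=(rng.uniform(8, 40), rng.uniform(0, 6)),
        map_quality=(rng.uniform(8, 60), rng.uniform(0, 4)),
        flank_quality=(rng.uniform(8, 40), rng.uniform(0, 6)),
        strand_balance=rng.choice([0.0, 0.1, 0.5, 0.9, 1.0]),
        positional_bias=rng.choice(["none", "none", "start", "end"]),
        positional_bias_fraction=rng.choice([0.5, 0.9, 0.95, 1.0]),
        mismatch_mean=rng.uniform(0, 3),
        proper_pair_rate=rng.choice([0.5, 0.9, 1.0]),
        indel_rate=rng.choice([0.0, 0.0, 0.1]),
        other_allele_rate=rng.choice([0.0, 0.0, 0.02, 0.1]),
        seed=rng.randrange(2**31),
    )


# ---------------------------------------------------------------------------
# Independent expectation predicates (the truth-side oracle)
# ---------------------------------------------------------------------------
#
# These translate the published threshold tables directly over the raw
# observation lists with explicit loops.  They intentionally avoid
# summarize_column / ThresholdSet / detect_candidate so that agreement with
# the caller is a two-route check, not a tautology.


def _filtered(obs_list, min_bq=10, min_mq=10):
    return [
        o
        for o in obs_list
        if o.base != "N" and o.base_quality >= min_bq and o.map_quality >= min_mq
    ]


def _top_alt(obs_list, ref):
    counts = {}
    for o in obs_list:
        if o.base != ref:
            counts[o.base] = counts.get(o.base, 0) + 1
    best = None
    for b in "ACGT":
        if counts.get(b, 0) > 0 and (best is None or counts[b] > counts[best]):
            best = b
    return best


def _strand_biased(alt_obs) -> bool:
    if len(alt_obs) < 4:
        return False
    fwd = sum(1 for o in alt_obs if o.strand is Strand.FORWARD)
    return fwd / len(alt_obs) > 0.90 or (len(alt_obs) - fwd) / len(alt_obs) > 0.90


def independent_dom_expectation(column: PileupColumn) -> tuple[str, str] | None:
    """Expected DNA-only outcome: ("germline"|"somatic", alt) or None."""
    normal = _filtered(column.role_observations(SampleRole.NORMAL_DNA))
    ref = column.ref_base

    n_alt = _top_alt(normal, ref)
    if n_alt is not None:
        alt_obs = [o for o in normal if o.base == n_alt]
        # lenient candidate, then the germline profile
        if len(normal) >= 4 and len(alt_obs) >= 2:
            other = len(normal) - sum(1 for o in normal if o.base == ref) - len(alt_obs)
            ok = (
                len(normal) >= 10
                and len(alt_obs) >= 4
                and len(alt_obs) / len(normal) >= 0.10
                and sum(o.base_quality for o in alt_obs) / len(alt_obs) >= 20
                and not _strand_biased(alt_obs)
                and other / len(normal) <= 0.02
            )
            if ok:
                return ("germline", n_alt)

    tumor = _filtered(column.role_observations(SampleRole.TUMOR_DNA))
    t_alt = _top_alt(tumor, ref)
    if t_alt is None:
        return None
    t_alt_obs = [o for o in tumor if o.base == t_alt]
    if len(tumor) < 4 or len(t_alt_obs) < 2:
        return None
    t_other = len(tumor) - sum(1 for o in tumor if o.base == ref) - len(t_alt_obs)
    if not (
        len(tumor) >= 10
        and len(t_alt_obs) >= 4
        and len(t_alt_obs) / len(tumor) >= 0.10
        and sum(o.base_quality for o in t_alt_obs) / len(t_alt_obs) >= 20
        and not _strand_biased(t_alt_obs)
        and t_other / len(tumor) <= 0.02
    ):
        return None
    n_alt_obs = [o for o in normal if o.base == t_alt]
    n_other = len(normal) - sum(1 for o in normal if o.base == ref) - len(n_alt_obs)
    if not (
        len(normal) >= 10
        and len(n_alt_obs) / len(normal) <= 0.02
        and n_other / len(normal) <= 0.02
    ):
        return None
    return ("somatic", t_alt)


def independent_tbm_expectation(column: PileupColumn) -> tuple[str, str] | None:
    """Expected triple-sample outcome: ("somatic", alt) or None."""
    rna = _filtered(column.role_observations(SampleRole.TUMOR_RNA))
    ref = column.ref_base
    alt = _top_alt(rna, ref)
    if alt is None:
        return None
    rna_alt = [o for o in rna if o.base == alt]
    if len(rna) < 4 or len(rna_alt) < 2:
        return None
    rna_other = len(rna) - sum(1 for o in rna if o.base == ref) - len(rna_alt)
    if not (
        len(rna) >= 10
        and len(rna_alt) >= 4
        and len(rna_alt) / len(rna) >= 0.10
        and sum(o.base_quality for o in rna_alt) / len(rna_alt) >= 15
        and not _strand_biased(rna_alt)
        and rna_other / len(rna) <= 0.02
    ):
        return None

    tumor = _filtered(column.role_observations(SampleRole.TUMOR_DNA))
    t_alt_obs = [o for o in tumor if o.base == alt]
    t_other = len(tumor) - sum(1 for o in tumor if o.base == ref) - len(t_alt_obs)
    if not (
        len(tumor) >= 1
        and len(t_alt_obs) >= 1
        and sum(o.base_quality for o in t_alt_obs) / len(t_alt_obs) >= 15
        and not _strand_biased(t_alt_obs)
        and t_other / len(tumor) <= 0.10
    ):
        return None

    normal = _filtered(column.role_observations(SampleRole.NORMAL_DNA))
    n_alt_obs = [o for o in normal if o.base == alt]
    n_other = len(normal) - sum(1 for o in normal if o.base == ref) - len(n_alt_obs)
    if not (
        len(normal) >= 10
        and len(n_alt_obs) / len(normal) <= 0.10
        and n_other / len(normal) <= 0.10
    ):
        return None

    start = sum(1 for o in rna_alt if o.offset_in_read / o.read_length < 1 / 3)
    end = sum(1 for o in rna_alt if o.offset_in_read / o.read_length >= 2 / 3)
    if start / len(rna_alt) >= 0.95 or end / len(rna_alt) >= 0.95:
        return None
    return ("somatic", alt)


# ---------------------------------------------------------------------------
# Dataset emission
# ---------------------------------------------------------------------------

TRUTH_COLUMNS = (
    "chrom",
    "pos1",
    "refBase",
    "altBase",
    "normalVaf",
    "dnaVaf",
    "rnaVaf",
    "expectDomGermline",
    "expectDomSomatic",
    "expectTbmSomatic",
)


def generate_dataset(
    n_columns: int,
    out_pileup: str | Path | IO[str],
    out_truth: str | Path | IO[str],
    seed: int = 0,
    spec_sampler: Callable[[random.Random, int], SynthColumnSpec] | None = None,
) -> list[PileupColumn]:
    """Generate ``n_columns`` columns, write them in the pileup TSV dialect
    plus a truth TSV carrying the true per-role VAFs and the independent
    oracle's expected outcomes."""
    rng = random.Random(seed)
    sampler = spec_sampler or (lambda r, i: random_spec(r, pos=i))
    columns: list[PileupColumn] = []
    truth_rows: list[Sequence[str]] = []
    for i in range(n_columns):
        spec = sampler(rng, i)
        column = generate_column(spec, random.Random(spec.seed))
        columns.append(column)
        dom = independent_dom_expectation(column)
        tbm = independent_tbm_expectation(column)
        truth_rows.append(
            (
                column.chrom,
                str(column.pos + 1),
                spec.ref_base,
                spec.alt_base,
                f"{spec.true_vaf.get(SampleRole.NORMAL_DNA, 0.0):.4f}",
                f"{spec.true_vaf.get(SampleRole.TUMOR_DNA, 0.0):.4f}",
                f"{spec.true_vaf.get(SampleRole.TUMOR_RNA, 0.0):.4f}",
                "1" if dom is not None and dom[0] == "germline" else "0",
                "1" if dom is not None and dom[0] == "somatic" else "0",
                "1" if tbm is not None else "0",
            )
        )
    write_pileup_tsv(columns, out_pileup)

    def _write_truth(handle: IO[str]) -> None:
        handle.write("\t".join(TRUTH_COLUMNS) + "\n")
        for row in truth_rows:
            handle.write("\t".join(row) + "\n")

    if hasattr(out_truth, "write"):
        _write_truth(out_truth)  # type: ignore[arg-type]
    else:
        with open(out_truth, "w") as handle:
            _write_truth(handle)
    return columns
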
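"""Shared builders for observation-level fixtures."""

from __future__ import annotations

import itertools

import pytest

from triplecall.read_model import (
    PileupColumn,
    ReadObservation,
    SampleRole,
    Strand,
)

_counter = itertools.count()


def make_obs(
    base: str = "T",
    *,
    base_quality: int = 30,
    map_quality: int = 60,
    strand: Strand | str = Strand.FORWARD,
    offset: int = 50,
    read_length: int = 100,
    properly_paired: bool = True,
    mismatch_count: int = 0,
    has_indel: bool = False,
    flank_qualities: tuple[int, ...] = (30,) * 10,
    role: SampleRole = SampleRole.TUMOR_DNA,
    read_id: str | None = None,
    read_sequence: str | None = None,
) -> ReadObservation:
    if isinstance(strand, str):
        strand = Strand(strand)
    return ReadObservation(
        read_id=read_id or f"read{next(_counter)}",
        base=base,
        base_quality=base_quality,
        map_quality=map_quality,
        strand=strand,
        offset_in_read=offset,
        read_length=read_length,
        properly_paired=properly_paired,
        mismatch_count=mismatch_count,
        has_indel_alignment=has_indel,
        flank_qualities=flank_qualities,
        sample_role=role,
        read_sequence=read_sequence,
    )


def balanced(n: int, base: str, role: SampleRole, **kwargs) -> list[ReadObservation]:
    """n observations with alternating strands (as balanced as n allows)."""
    return [
        make_obs(
            base,
            role=role,
            strand=Strand.FORWARD if i % 2 == 0 else Strand.REVERSE,
            **kwargs,
        )
        for i in range(n)
    ]


def make_column(
    ref: str = "G",
    pos: int = 100,
    chrom: str = "chr1",
    normal: list[ReadObservation] | None = None,
    tumor: list[ReadObservation] | None = None,
    rna: list[ReadObservation] | None = None,
) -> PileupColumn:
    observations = {}
    if normal is not None:
        observations[SampleRole.NORMAL_DNA] = normal
    if tumor is not None:
        observations[SampleRole.TUMOR_DNA] = tumor
    if rna is not None:
        observations[SampleRole.TUMOR_RNA] = rna
    return PileupColumn(chrom=chrom, pos=pos, ref_base=ref, observations=observations)


@pytest.fixture
def simple_somatic_column() -> PileupColumn:
    """Clean somatic site: normal 30/0, tumor 30/12 alt T, RNA 20/8 alt T."""
    return make_column(
        ref="G",
        normal=balanced(30, "G", SampleRole.NORMAL_DNA),
        tumor=balanced(18, "G", SampleRole.TUMOR_DNA) + balanced(12, "T", SampleRole.TUMOR_DNA, base_quality=25),
        rna=balanced(12, "G", SampleRole.TUMOR_RNA) + balanced(8, "T", SampleRole.TUMOR_RNA),
    )
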
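"""Observation model, column summaries and the two input routes."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from triplecall.read_model import (
    PileupParseError,
    SampleRole,
    Strand,
    read_bam_pileup,
    read_pileup_tsv,
    summarize_column,
    write_pileup_tsv,
)

from conftest import make_column, make_obs


class TestSummarizeColumn:
    def test_hand_counted_mixture(self):
        # 6 ref G + 4 alt T (2 forward, 2 reverse), all quality 30
        obs = [make_obs("G") for _ in range(6)] + [
            make_obs("T", strand=Strand.FORWARD),
            make_obs("T", strand=Strand.FORWARD),
            make_obs("T", strand=Strand.REVERSE),
            make_obs("T", strand=Strand.REVERSE),
        ]
        s = summarize_column(obs, "G", 10, 10)
        assert (s.depth, s.alt_allele, s.alt_depth) == (10, "T", 4)
        assert s.alt_fraction == pytest.approx(0.4)
        assert s.alt_forward_fraction == pytest.approx(0.5)
        assert s.avg_alt_base_quality == pytest.approx(30.0)
        assert s.other_fraction == 0.0

    def test_all_reference(self):
        s = summarize_column([make_obs("G") for _ in range(10)], "G")
        assert s.alt_allele is None and s.alt_depth == 0

    def test_low_quality_alt_reads_excluded_from_all_counts(self):
        obs = [make_obs("G") for _ in range(6)] + [
            make_obs("T", base_quality=5) for _ in range(4)
        ]
        s = summarize_column(obs, "G", min_base_quality=10)
        assert s.depth == 6 and s.alt_depth == 0

    def test_n_bases_never_counted(self):
        obs = [make_obs("G"), make_obs("N"), make_obs("T"), make_obs("T")]
        s = summarize_column(obs, "G")
        assert s.depth == 3 and s.alt_depth == 2

    def test_tie_break_is_lexicographic(self):
        obs = [make_obs("T"), make_obs("A"), make_obs("G")]
        assert summarize_column(obs, "G").alt_allele == "A"

    def test_forced_alt_allele(self):
        obs = [make_obs("G")] * 5 + [make_obs("A")] * 3 + [make_obs("T")]
        s = summarize_column(obs, "G", alt_allele="T")
        assert s.alt_depth == 1
        assert s.other_fraction == pytest.approx(3 / 9)

    def test_empty_observations(self):
        s = summarize_column([], "G")
        assert s.depth == 0 and s.alt_allele is None and s.alt_fraction == 0.0


# -- property checks ---------------------------------------------------------

observation_lists = st.lists(
    st.builds(
        make_obs,
        st.sampled_from("ACGTN"),
        base_quality=st.integers(0, 45),
        map_quality=st.integers(0, 60),
        strand=st.sampled_from([Strand.FORWARD, Strand.REVERSE]),
    ),
    max_size=40,
)


@settings(deadline=None, max_examples=150, derandomize=True)
@given(observation_lists, st.integers(0, 45), st.integers(0, 60))
def test_summary_matches_naive_recount(obs, min_bq, min_mq):
    """The summary must equal a direct recount over the raw list."""
    s = summarize_column(obs, "G", min_bq, min_mq)
    kept = [
        o
        for o in obs
        if o.base != "N" and o.base_quality >= min_bq and o.map_quality >= min_mq
    ]
    assert s.depth == len(kept)
    if s.alt_allele is not None:
        assert s.alt_depth == sum(1 for o in kept if o.base == s.alt_allele)
        # no other non-ref allele may exceed the chosen one
        for b in "ACT":
            if b not in ("G", s.alt_allele):
                assert sum(1 for o in kept if o.base == b) <= s.alt_depth
    assert s.alt_fraction == (s.alt_depth / s.depth if s.depth else 0.0)


@settings(deadline=None, max_examples=100, derandomize=True)
@given(observation_lists, st.randoms(use_true_random=False))
def test_summary_invariant_under_permutation(obs, rng):
    before = summarize_column(obs, "G", 10, 10)
    shuffled = list(obs)
    rng.shuffle(shuffled)
    assert summarize_column(shuffled, "G", 10, 10) == before


@settings(deadline=None, max_examples=100, derandomize=True)
@given(observation_lists, st.integers(0, 40), st.integers(0, 40))
def test_depth_monotone_in_quality_cuts(obs, bq, mq):
    lower = summarize_column(obs, "G", bq, mq).depth
    higher = summarize_column(obs, "G", bq + 5, mq + 5).depth
    assert higher <= lower


# -- pileup TSV dialect ------------------------------------------------------


class TestPileupTsv:
    def test_round_trip(self, tmp_path):
        col = make_column(
            normal=[make_obs("G", role=SampleRole.NORMAL_DNA)],
            tumor=[make_obs("T", read_sequence="ACGT")],
            rna=[make_obs("T", role=SampleRole.TUMOR_RNA, flank_qualities=(1, 2, 3))],
        )
        path = tmp_path / "p.tsv"
        write_pileup_tsv([col], path)
        (parsed,) = list(read_pileup_tsv(path))
        assert (parsed.chrom, parsed.pos, parsed.ref_base) == (col.chrom, col.pos, "G")
        for role in SampleRole:
            assert parsed.role_observations(role) == col.role_observations(role)

    def test_empty_file_yields_empty_stream(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        assert list(read_pileup_tsv(path)) == []

    def test_header_only_yields_empty_stream(self, tmp_path):
        path = tmp_path / "p.tsv"
        write_pileup_tsv([], path)
        assert list(read_pileup_tsv(path)) == []

    def test_invalid_base_names_line(self, tmp_path):
        path = tmp_path / "p.tsv"
        write_pileup_tsv([make_column(tumor=[make_obs("T")])], path)
        broken = path.read_text().replace("\tT\t", "\tZ\t")
        path.write_text(broken)
        with pytest.raises(PileupParseError, match="line 2"):
            list(read_pileup_tsv(path))

    def test_missing_field_reports_line(self, tmp_path):
        path = tmp_path / "p.tsv"
        write_pileup_tsv([make_column(tumor=[make_obs("T")])], path)
        lines = path.read_text().splitlines()
        lines[1] = "\t".join(lines[1].split("\t")[:-2])
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(PileupParseError, match="line 2"):
            list(read_pileup_tsv(path))


# -- BAM route ---------------------------------------------------------------


REF_SEQ = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT"  # 40 bp


def _write_bam(tmp_path, name, reads):
    """reads: list of (qname, flag, pos1, cigar, seq, extra_tags)."""
    import pysam

    sam = tmp_path / f"{name}.sam"
    lines = ["@HD\tVN:1.6\tSO:coordinate", f"@SQ\tSN:ref\tLN:{len(REF_SEQ)}"]
    for qname, flag, pos1, cigar, seq, tags in reads:
        qual = "I" * len(seq)
        lines.append(
            f"{qname}\t{flag}\tref\t{pos1}\t60\t{cigar}\t*\t0\t0\t{seq}\t{qual}\t{tags}"
        )
    sam.write_text("\n".join(lines) + "\n")
    bam = tmp_path / f"{name}.bam"
    pysam.sort("-o", str(bam), str(sam))
    pysam.index(str(bam))
    return bam


@pytest.fixture
def reference_fasta(tmp_path):
    import pysam

    path = tmp_path / "ref.fa"
    path.write_text(f">ref\n{REF_SEQ}\n")
    pysam.faidx(str(path))
    return path


def test_bam_triplet_single_read_per_role(tmp_path, reference_fasta):
    """One read per role over the same base gives one observation per role."""
    # 10 bp read starting at 1-based position 5; base at ref pos 10 (0-based 9) is offset 5
    seq = REF_SEQ[4:14]
    mutated = seq[:5] + "A" + seq[6:]
    paths = {}
    for role, name, seq_used in [
        (SampleRole.NORMAL_DNA, "n", seq),
        (SampleRole.TUMOR_DNA, "t", mutated),
        (SampleRole.TUMOR_RNA, "r", mutated),
    ]:
        nm = sum(1 for a, b in zip(seq_used, seq) if a != b)
        paths[role] = _write_bam(
            tmp_path, name, [(f"{name}1", 0, 5, "10M", seq_used, f"NM:i:{nm}")]
        )
    columns = {
        c.pos: c for c in read_bam_pileup(paths, reference_fasta, region=("ref", 0, 40))
    }
    col = columns[9]
    assert col.ref_base == REF_SEQ[9]
    for role in SampleRole:
        (obs,) = col.role_observations(role)
        assert obs.offset_in_read == 5 and obs.read_length == 10
        assert obs.base == ("A" if role != SampleRole.NORMAL_DNA else REF_SEQ[9])
    (tumor_obs,) = col.role_observations(SampleRole.TUMOR_DNA)
    assert tumor_obs.mismatch_count == 1
    assert tumor_obs.read_sequence == mutated


def test_single_end_read_properly_paired_convention(tmp_path, reference_fasta):
    bam = _write_bam(tmp_path, "se", [("se1", 0, 1, "10M", REF_SEQ[:10], "NM:i:0")])
    paths = {SampleRole.TUMOR_RNA: bam}
    col = next(iter(read_bam_pileup(paths, reference_fasta)))
    assert col.role_observations(SampleRole.TUMOR_RNA)[0].properly_paired is True
    col_strict = next(
        iter(read_bam_pileup(paths, reference_fasta, single_end_properly_paired=False))
    )
    assert col_strict.role_observations(SampleRole.TUMOR_RNA)[0].properly_paired is False


def test_deletion_alignment_flags_indel(tmp_path, reference_fasta):
    # 5M2D5M: alignment spans a deletion
    seq = REF_SEQ[0:5] + REF_SEQ[7:12]
    bam = _write_bam(tmp_path, "d", [("d1", 0, 1, "5M2D5M", seq, "NM:i:2")])
    columns = list(read_bam_pileup({SampleRole.TUMOR_DNA: bam}, reference_fasta))
    obs = columns[0].role_observations(SampleRole.TUMOR_DNA)[0]
    assert obs.has_indel_alignment is True
    # NM counts the 2 deleted bases; the mismatch count must not
    assert obs.mismatch_count == 0


def test_missing_index_raises(tmp_path, reference_fasta):
    import pysam

    sam = tmp_path / "x.sam"
    sam.write_text("@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:ref\tLN:40\n")
    bam = tmp_path / "x.bam"
    pysam.sort("-o", str(bam), str(sam))
    (tmp_path / "x.bam.bai").unlink(missing_ok=True)
    with pytest.raises((OSError, ValueError)):
        list(
            read_bam_pileup(
                {SampleRole.TUMOR_DNA: bam}, reference_fasta, region=("ref", 0, 40)
            )
        )
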
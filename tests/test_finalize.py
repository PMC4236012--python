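"""Perfect-read support, merging, VCF output and reporting."""

from __future__ import annotations

import io

import pytest

from triplecall.calling import VariantCall
from triplecall.finalize import (
    PerfectReadParams,
    filter_report,
    format_vaf_percent,
    is_perfect_read,
    merge_calls,
    read_support_filter,
    write_vcf,
)
from triplecall.filters import FilterVerdict
from triplecall.read_model import SampleRole, Strand, summarize_column

from conftest import balanced, make_column, make_obs

PERFECT = dict(
    base_quality=30,
    map_quality=30,
    flank_qualities=(30,) * 10,
    properly_paired=True,
    mismatch_count=0,
    has_indel=False,
)


class TestIsPerfectRead:
    def test_exactly_at_every_threshold(self):
        obs = make_obs(
            "T",
            base_quality=10,
            map_quality=10,
            flank_qualities=(10,) * 10,
            mismatch_count=3,
        )
        assert is_perfect_read(obs)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"map_quality": 9},
            {"base_quality": 9},
            {"flank_qualities": (30,) * 9 + (9,)},
            {"properly_paired": False},
            {"mismatch_count": 4},  # "fewer than four" is exclusive
            {"has_indel": True},
        ],
    )
    def test_each_criterion_disqualifies(self, kwargs):
        assert not is_perfect_read(make_obs("T", **{**PERFECT, **kwargs}))


def _call(label="DNA_only", **kwargs):
    defaults = dict(
        chrom="chr1", pos=100, ref="G", alt="T", category="somatic", origin="DOM"
    )
    defaults.update(kwargs)
    return VariantCall(label=label, **defaults)


class TestReadSupportFilter:
    def test_four_perfect_alt_reads_balanced_pass(self):
        col = make_column(
            tumor=balanced(4, "G", SampleRole.TUMOR_DNA)
            + balanced(4, "T", SampleRole.TUMOR_DNA)
        )
        assert read_support_filter(_call(), col).passed

    def test_three_perfect_alt_reads_fail(self):
        col = make_column(
            tumor=balanced(5, "G", SampleRole.TUMOR_DNA)
            + balanced(3, "T", SampleRole.TUMOR_DNA)
        )
        verdict = read_support_filter(_call(), col)
        assert verdict.failed_filters == ("perfect_support",)

    def test_imperfect_reads_do_not_count(self):
        tumor = balanced(4, "G", SampleRole.TUMOR_DNA) + [
            make_obs("T", role=SampleRole.TUMOR_DNA, mismatch_count=4) for _ in range(4)
        ]
        verdict = read_support_filter(_call(), make_column(tumor=tumor))
        assert not verdict.passed

    def test_one_sided_perfect_strands_fail(self):
        # 5 perfect alt reads but every perfect read (ref+alt) is forward
        tumor = [
            make_obs("T", role=SampleRole.TUMOR_DNA, strand=Strand.FORWARD)
            for _ in range(5)
        ]
        verdict = read_support_filter(_call(), make_column(tumor=tumor))
        assert verdict.failed_filters == ("perfect_strand_bias",)

    def test_reference_reads_enter_the_strand_denominator(self):
        # 5 forward alt + 5 reverse ref: 50% per strand over perfect reads
        tumor = [
            make_obs("T", role=SampleRole.TUMOR_DNA, strand=Strand.FORWARD)
            for _ in range(5)
        ] + [
            make_obs("G", role=SampleRole.TUMOR_DNA, strand=Strand.REVERSE)
            for _ in range(5)
        ]
        assert read_support_filter(_call(), make_column(tumor=tumor)).passed

    def test_rescued_call_checked_in_rna(self):
        col = make_column(
            tumor=balanced(1, "T", SampleRole.TUMOR_DNA),
            rna=balanced(6, "G", SampleRole.TUMOR_RNA)
            + balanced(6, "T", SampleRole.TUMOR_RNA),
        )
        assert read_support_filter(_call(label="RNA_Rescue"), col).passed
        assert not read_support_filter(_call(label="DNA_only"), col).passed

    def test_confirmed_call_passes_when_either_sample_passes(self):
        col = make_column(
            tumor=balanced(2, "T", SampleRole.TUMOR_DNA),  # too few in DNA
            rna=balanced(6, "T", SampleRole.TUMOR_RNA)
            + balanced(6, "G", SampleRole.TUMOR_RNA),
        )
        assert read_support_filter(_call(label="RNA_Confirmation"), col).passed


class TestMergeCalls:
    def test_shared_site_becomes_rna_confirmation(self):
        merged = merge_calls([_call(label=None)], [_call(label=None, origin="TBM")])
        assert len(merged) == 1
        assert merged[0].origin == "both" and merged[0].label == "RNA_Confirmation"

    def test_tbm_only_site_is_rna_rescue(self):
        merged = merge_calls([], [_call(label=None, origin="TBM")])
        assert merged[0].label == "RNA_Rescue"

    def test_empty_tbm_all_dna_only(self):
        merged = merge_calls([_call(label=None), _call(label=None, pos=200)], [])
        assert [c.label for c in merged] == ["DNA_only", "DNA_only"]

    def test_conflicting_alts_both_kept(self):
        merged = merge_calls(
            [_call(label=None, alt="T")], [_call(label=None, alt="C", origin="TBM")]
        )
        assert {(c.alt, c.label) for c in merged} == {
            ("T", "DNA_only"),
            ("C", "RNA_Rescue"),
        }

    def test_merge_commutative_in_input_order(self):
        dom = [_call(label=None, pos=p) for p in (300, 100)]
        tbm = [_call(label=None, pos=100, origin="TBM")]
        a = merge_calls(list(reversed(dom)), tbm)
        b = merge_calls(dom, tbm)
        assert [(c.pos, c.label) for c in a] == [(c.pos, c.label) for c in b]

    def test_germline_calls_pass_through_unlabeled(self):
        germline = _call(label=None, category="germline")
        merged = merge_calls([germline], [])
        assert merged[0].label is None and merged[0].category == "germline"


class TestVafPercent:
    @pytest.mark.parametrize(
        "alt, depth, expected",
        [(20, 40, 50), (31, 34, 91), (4, 64, 6), (6, 10, 60), (8, 57, 14),
         (22, 62, 35), (0, 10, 0), (1, 200, 1), (1, 201, 0)],
    )
    def test_rounding_half_away_from_zero(self, alt, depth, expected):
        assert format_vaf_percent(alt, depth) == expected

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            format_vaf_percent(0, 0)


class TestWriteVcf:
    def _passing_call(self):
        call = _call(label="DNA_only")
        call.summaries[SampleRole.TUMOR_DNA] = summarize_column(
            balanced(6, "G", SampleRole.TUMOR_DNA)
            + balanced(4, "T", SampleRole.TUMOR_DNA),
            "G",
        )
        return call

    def test_positions_are_one_based_and_filter_pass(self):
        text = write_vcf([self._passing_call()])
        data = [l for l in text.splitlines() if not l.startswith("#")]
        assert len(data) == 1
        fields = data[0].split("\t")
        assert fields[1] == "101"  # internal 100
        assert fields[6] == "PASS"
        assert "LABEL=DNA_only" in fields[7]

    def test_zero_calls_is_header_only(self):
        text = write_vcf([])
        assert all(line.startswith("#") for line in text.splitlines())
        assert text.startswith("##fileformat=VCFv4.2")

    def test_rendering_is_deterministic(self):
        calls = [self._passing_call(), self._passing_call()]
        calls[1].pos = 50
        assert write_vcf(calls) == write_vcf(list(reversed(calls)))

    def test_round_trip_through_pysam(self, tmp_path):
        import pysam

        call = self._passing_call()
        failed = _call(label="RNA_Rescue", pos=200, origin="TBM", alt="C")
        failed.verdicts.append(FilterVerdict(("perfect_support",)))
        failed.summaries[SampleRole.TUMOR_RNA] = summarize_column(
            balanced(5, "C", SampleRole.TUMOR_RNA), "G"
        )
        path = tmp_path / "out.vcf"
        write_vcf([call, failed], out=path)
        with pysam.VariantFile(str(path)) as vcf:
            records = list(vcf)
        assert [(r.chrom, r.pos, r.ref, r.alts[0]) for r in records] == [
            ("chr1", 101, "G", "T"),
            ("chr1", 201, "G", "C"),
        ]
        assert records[0].info["LABEL"] == "DNA_only"
        assert list(records[1].filter) == ["perfect_support"]
        assert records[0].samples["TUMOR_DNA"]["DP"] == 10


class TestFilterReport:
    def test_counts_attribute_first_failure_and_reconcile(self):
        rejected = []
        for i, names in enumerate(
            [("blacklist", "strand_bias"), ("strand_bias",), ("blacklist",)]
        ):
            call = _call(label=None, pos=i)
            call.verdicts.append(FilterVerdict(names))
            rejected.append(call)
        report = filter_report(rejected)
        assert report["DOM"]["blacklist"] == 2  # double failure counted once
        assert report["DOM"]["strand_bias"] == 1
        assert sum(report["DOM"].values()) == len(rejected)

    def test_all_passing_gives_empty_report(self):
        assert filter_report([_call(label=None)]) == {}
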
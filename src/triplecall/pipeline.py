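"""End-to-end call pipeline over a pileup column stream.

read → lenient detection → DNA-only and triple-sample evaluation (in
parallel per column) → merge & classify → perfect-read support filter →
VCF + per-filter rejection report.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

from .calling import (
    DOM_PROFILES,
    TBM_PROFILES,
    AnnotationSets,
    VariantCall,
    dom_candidate,
    tbm_candidate,
)
from .detection import DetectionParams
from .filters import RemapAligner, ThresholdSet
from .finalize import (
    PerfectReadParams,
    filter_report,
    merge_calls,
    read_support_filter,
)
from .read_model import PileupColumn

__all__ = ["CallRunResult", "run_call"]

logger = logging.getLogger(__name__)


@dataclass
class CallRunResult:
    """Everything a calling run produced."""

    calls: list[VariantCall] = field(default_factory=list)  # final, passing
    rejected: list[VariantCall] = field(default_factory=list)  # failed candidates
    n_columns: int = 0
    n_dom_candidates: int = 0
    n_tbm_candidates: int = 0

    @property
    def somatic_calls(self) -> list[VariantCall]:
        return [c for c in self.calls if c.category == "somatic"]

    @property
    def germline_calls(self) -> list[VariantCall]:
        return [c for c in self.calls if c.category == "germline"]

    def report(self) -> dict[str, Counter]:
        """Rejected-candidate counts per calling path, keyed by the first
        failed filter."""
        return filter_report(self.rejected)


def run_call(
    columns: Iterable[PileupColumn],
    regions: AnnotationSets | None = None,
    detection: DetectionParams = DetectionParams(),
    dom_profiles: dict[str, ThresholdSet] = DOM_PROFILES,
    tbm_profiles: dict[str, ThresholdSet] = TBM_PROFILES,
    perfect_read_params: PerfectReadParams = PerfectReadParams(),
    remap_aligner: RemapAligner | None = None,
    apply_dbsnp_to_dom: bool = False,
) -> CallRunResult:
    """Run the full calling pipeline and return calls plus accounting.

    The perfect-read support filter applies to merged *somatic* calls
    only; germline calls are emitted (VCF-tagged) without it.
    """
    result = CallRunResult()
    dom_pass: list[VariantCall] = []
    tbm_pass: list[VariantCall] = []
    columns_by_site: dict[tuple[str, int], PileupColumn] = {}

    for column in columns:
        result.n_columns += 1
        dom = dom_candidate(
            column,
            profiles=dom_profiles,
            regions=regions,
            detection=detection,
            apply_dbsnp=apply_dbsnp_to_dom,
        )
        if dom is not None:
            result.n_dom_candidates += 1
            if dom.passed:
                dom_pass.append(dom)
                columns_by_site[(column.chrom, column.pos)] = column
            else:
                result.rejected.append(dom)
        tbm = tbm_candidate(
            column,
            profiles=tbm_profiles,
            regions=regions,
            detection=detection,
            remap_aligner=remap_aligner,
        )
        if tbm is not None:
            result.n_tbm_candidates += 1
            if tbm.passed:
                tbm_pass.append(tbm)
                columns_by_site[(column.chrom, column.pos)] = column
            else:
                result.rejected.append(tbm)

    merged = merge_calls(dom_pass, tbm_pass)
    for call in merged:
        if call.category != "somatic":
            result.calls.append(call)
            continue
        column = columns_by_site[(call.chrom, call.pos)]
        verdict = read_support_filter(call, column, perfect_read_params)
        call.verdicts.append(verdict)
        if verdict.passed:
            result.calls.append(call)
        else:
            result.rejected.append(call)

    logger.info(
        "processed %d columns: %d DNA-only candidates, %d triple-sample candidates, "
        "%d final calls (%d somatic, %d germline), %d rejected",
        result.n_columns,
        result.n_dom_candidates,
        result.n_tbm_candidates,
        len(result.calls),
        len(result.somatic_calls),
        len(result.germline_calls),
        len(result.rejected),
    )
    return result
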
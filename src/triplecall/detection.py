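"""Lenient initial candidate detection.

Every downstream decision starts from a deliberately permissive scan: a
position becomes a candidate for a sample role when, after discarding bases
below the quality cuts, the overall depth and the depth of the best
non-reference allele clear small minimums.  The defaults (depth >= 4,
variant depth >= 2, base quality >= 10, mapping quality >= 10) keep
essentially every plausible variant alive for the stricter filter chains.
"""

from __future__ import annotations

from dataclasses import dataclass

from .read_model import AlleleSummary, PileupColumn, SampleRole, summarize_column

__all__ = ["DetectionParams", "detect_candidate"]


@dataclass(frozen=True)
class DetectionParams:
    min_total_depth: int = 4
    min_variant_depth: int = 2
    min_base_quality: int = 10
    min_map_quality: int = 10

    def __post_init__(self) -> None:
        if min(
            self.min_total_depth,
            self.min_variant_depth,
            self.min_base_quality,
            self.min_map_quality,
        ) < 0:
            raise ValueError("detection thresholds must be non-negative")
        if self.min_variant_depth > self.min_total_depth:
            raise ValueError("min_variant_depth cannot exceed min_total_depth")


def detect_candidate(
    column: PileupColumn,
    role: SampleRole,
    params: DetectionParams = DetectionParams(),
) -> AlleleSummary | None:
    """Return the role's allele summary when the column is a candidate
    variant site for that sample, else ``None``.

    A candidate requires quality-filtered depth >= ``min_total_depth`` and
    alt depth >= ``min_variant_depth``.
    """
    if not isinstance(role, SampleRole):
        raise ValueError(f"unknown sample role {role!r}")
    summary = summarize_column(
        column.role_observations(role),
        column.ref_base,
        min_base_quality=params.min_base_quality,
        min_map_quality=params.min_map_quality,
    )
    if summary.depth >= params.min_total_depth and summary.alt_depth >= params.min_variant_depth:
        return summary
    return None
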
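"""Interval and position collections backing the annotation filters.

The caller consults several externally supplied genomic annotations:

* an accessible-genome *blacklist* (regions too repetitive or ambiguous for
  reliable calling), as BED intervals;
* known-polymorphism position lists in the style of dbSNP (one current
  "common" list and one of positions retired from later database versions
  as artifacts);
* predicted *pseudogene* intervals and *high-similarity gene family*
  intervals (ribosomal proteins, HLAs, immunoglobulins, ...), both prone to
  cross-mapping artifacts in RNA-seq;
* a catalogue of somatic mutations observed in other cancer studies
  (COSMIC-style), as a position list, used to rescue unvalidated calls.

All of these are modeled as a :class:`RegionSet`: either a per-chromosome
interval tree (BED input, 0-based half-open) or a per-chromosome position
set (two-column ``chrom pos`` text, 1-based positions).  Chromosome names
are matched with any ``chr`` prefix stripped, since the source files mix
conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from intervaltree import IntervalTree

__all__ = ["RegionSet", "load_bed", "load_positions", "contains"]


def _norm_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


@dataclass
class RegionSet:
    """A named collection of genomic intervals or single positions."""

    name: str
    mode: str = "interval"  # "interval" | "position"
    intervals: dict[str, IntervalTree] = field(default_factory=dict)
    positions: dict[str, set[int]] = field(default_factory=dict)

    def contains(self, chrom: str, pos: int) -> bool:
        """True iff 0-based ``pos`` falls in an interval or equals a stored
        position."""
        chrom = _norm_chrom(chrom)
        if self.mode == "interval":
            tree = self.intervals.get(chrom)
            return bool(tree is not None and tree.overlaps_point(pos))
        return pos in self.positions.get(chrom, ())

    def __len__(self) -> int:
        if self.mode == "interval":
            return sum(len(t) for t in self.intervals.values())
        return sum(len(p) for p in self.positions.values())


def load_bed(path: str | Path, name: str | None = None) -> RegionSet:
    """Load a BED3+ file into an interval-mode :class:`RegionSet`.

    Intervals are stored 0-based half-open; overlapping or book-ended input
    intervals are merged.
    """
    rs = RegionSet(name=name or Path(path).stem, mode="interval")
    with open(path) as handle:
        for line_number, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}: line {line_number}: expected >=3 BED fields")
            chrom = _norm_chrom(fields[0])
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(
                    f"{path}: line {line_number}: non-integer BED coordinates"
                ) from None
            if start < 0 or start >= end:
                raise ValueError(
                    f"{path}: line {line_number}: invalid interval [{start}, {end})"
                )
            rs.intervals.setdefault(chrom, IntervalTree()).addi(start, end)
    for tree in rs.intervals.values():
        tree.merge_overlaps(strict=False)
    return rs


def load_positions(path: str | Path, name: str | None = None) -> RegionSet:
    """Load a two-column ``chrom pos`` text file (1-based positions, as the
    dbSNP/COSMIC-style exports print them) into a position-mode set;
    positions are stored 0-based."""
    rs = RegionSet(name=name or Path(path).stem, mode="position")
    with open(path) as handle:
        for line_number, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}: line {line_number}: expected 'chrom pos'")
            try:
                pos1 = int(fields[1])
            except ValueError:
                raise ValueError(f"{path}: line {line_number}: non-integer position") from None
            if pos1 < 1:
                raise ValueError(f"{path}: line {line_number}: position must be >=1")
            rs.positions.setdefault(_norm_chrom(fields[0]), set()).add(pos1 - 1)
    return rs


def contains(region_set: RegionSet, chrom: str, pos: int) -> bool:
    """Functional alias for :meth:`RegionSet.contains`."""
    return region_set.contains(chrom, pos)
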
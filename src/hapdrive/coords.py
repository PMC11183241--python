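"""Coordinate conventions, centralized.

VCF and GFF3 positions are 1-based inclusive; coverage bins and BED-style
interval files are 0-based half-open.  All in-memory interval lists
(exome masks, diploid regions, CNV intervals) use the 0-based half-open
convention; conversion happens only through these helpers.
"""

from __future__ import annotations

from bisect import bisect_right
from typing import Iterable, Sequence

Interval = tuple[str, int, int]  # chrom, start0, end0 (half-open)


def to_zero_based(start1: int, end1: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start1 - 1, end1


def to_one_based(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start0 + 1, end0


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent (start0, end0) intervals; result sorted."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


class IntervalSet:
    """Sorted, non-overlapping per-chromosome intervals with O(log n) lookup."""

    def __init__(self, intervals: Iterable[Interval]):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in intervals:
            if e <= s:
                raise ValueError(f"empty interval {chrom}:{s}-{e}")
            by_chrom.setdefault(chrom, []).append((s, e))
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        for chrom, ivals in by_chrom.items():
            merged = merge_intervals(ivals)
            self._starts[chrom] = [s for s, _ in merged]
            self._ends[chrom] = [e for _, e in merged]

    def contains(self, chrom: str, pos0: int) -> bool:
        starts = self._starts.get(chrom)
        if not starts:
            return False
        i = bisect_right(starts, pos0) - 1
        return i >= 0 and pos0 < self._ends[chrom][i]

    def overlaps(self, chrom: str, start0: int, end0: int) -> bool:
        starts = self._starts.get(chrom)
        if not starts:
            return False
        i = bisect_right(starts, start0) - 1
        if i >= 0 and start0 < self._ends[chrom][i]:
            return True
        i += 1
        return i < len(starts) and starts[i] < end0

    def near(self, chrom: str, pos0: int, flank: int) -> bool:
        """True if pos0 is within `flank` bp of any interval."""
        return self.overlaps(chrom, pos0 - flank, pos0 + flank + 1)

    def intervals(self) -> list[Interval]:
        out = []
        for chrom in sorted(self._starts):
            for s, e in zip(self._starts[chrom], self._ends[chrom]):
                out.append((chrom, s, e))
        return out

    def total_length(self) -> int:
        return sum(e - s for _, s, e in self.intervals())


def overlap_length(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Length of intersection of two half-open intervals."""
    return max(0, min(a_end, b_end) - max(a_start, b_start))
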
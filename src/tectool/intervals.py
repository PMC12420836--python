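"""Genomic interval primitives and overlap kernels.

Coordinates are 0-based, half-open ``[start, end)`` (BED convention)
throughout the package; readers convert any 1-based dialect at the boundary.

Two overlap predicates are distinguished because the analyses use both:

* :func:`overlaps` — strict sharing of at least one base pair; used when
  intersecting TE copies with differentially methylated regions.
* :func:`overlaps_maxgap` — the gap-based predicate used for peak/target
  co-occurrence summaries, where ``gap = max(0, max(starts) - min(ends))``
  and intervals within ``maxgap`` bases (touching counts as gap 0) match.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VALID_STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"


@dataclass(frozen=True)
class TECopy:
    """One located repeat copy with its RepeatMasker-style labels."""

    interval: GenomicInterval
    subfamily: str
    family: str
    te_class: str  # LINE, LTR, SINE, other

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def locus_id(self) -> str:
        iv = self.interval
        return f"{self.subfamily}|{iv.chrom}:{iv.start}-{iv.end}|{iv.strand}"


@dataclass(frozen=True)
class DMR:
    """A differentially methylated region (hypomethylated in the mutant)."""

    interval: GenomicInterval
    name: str = ""


@dataclass(frozen=True)
class DNMT3CTarget:
    """A DMR-overlapping, length-filtered TE copy."""

    te: TECopy
    supporting_dmrs: tuple[str, ...] = field(default_factory=tuple)

    @property
    def interval(self) -> GenomicInterval:
        return self.te.interval


def gap(a: GenomicInterval, b: GenomicInterval) -> int | None:
    """Distance in bp between two intervals; ``None`` across chromosomes.

    Overlapping or touching intervals have gap 0.
    """
    if a.chrom != b.chrom:
        return None
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the intervals share at least one base pair."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def overlaps_maxgap(a: GenomicInterval, b: GenomicInterval, maxgap: int = 0) -> bool:
    """True iff the intervals are within ``maxgap`` bp of each other."""
    if maxgap < 0:
        raise ValueError("maxgap must be >= 0")
    g = gap(a, b)
    return g is not None and g <= maxgap


class IntervalIndex:
    """Per-chromosome sorted-array index supporting batched overlap queries.

    Subject intervals are sorted by start; a running maximum of ends allows a
    binary-search sweep instead of the quadratic all-pairs scan (which the
    test suite keeps as the reference oracle).
    """

    def __init__(self, intervals: Sequence[GenomicInterval]):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            order = np.argsort([iv.start for iv in ivs], kind="stable")
            starts = np.array([ivs[i].start for i in order], dtype=np.int64)
            ends = np.array([ivs[i].end for i in order], dtype=np.int64)
            self._by_chrom[chrom] = (starts, ends, np.maximum.accumulate(ends))

    def any_overlap(self, query: GenomicInterval, maxgap: int | None = None) -> bool:
        """Does any subject overlap ``query``?

        ``maxgap=None`` uses the strict >=1 shared-bp predicate; an integer
        uses the gap-based predicate.
        """
        return self.count_overlaps(query, maxgap=maxgap) > 0

    def count_overlaps(self, query: GenomicInterval, maxgap: int | None = None) -> int:
        entry = self._by_chrom.get(query.chrom)
        if entry is None:
            return 0
        starts, ends, _ = entry
        if maxgap is None:
            lo, hi = query.start, query.end
            # subject.start < query.end and subject.end > query.start
            n_start_ok = int(np.searchsorted(starts, hi, side="left"))
            return int(np.count_nonzero(ends[:n_start_ok] > lo))
        if maxgap < 0:
            raise ValueError("maxgap must be >= 0")
        # subject.start - query.end <= maxgap and query.start - subject.end <= maxgap
        n_start_ok = int(np.searchsorted(starts, query.end + maxgap, side="right"))
        return int(np.count_nonzero(ends[:n_start_ok] >= query.start - maxgap))

    def overlapping_indices(
        self, query: GenomicInterval, maxgap: int | None = None
    ) -> np.ndarray:
        """Positions (within this chromosome's sorted order) of matching subjects."""
        entry = self._by_chrom.get(query.chrom)
        if entry is None:
            return np.empty(0, dtype=np.int64)
        starts, ends, _ = entry
        if maxgap is None:
            n_start_ok = int(np.searchsorted(starts, query.end, side="left"))
            mask = ends[:n_start_ok] > query.start
        else:
            if maxgap < 0:
                raise ValueError("maxgap must be >= 0")
            n_start_ok = int(np.searchsorted(starts, query.end + maxgap, side="right"))
            mask = ends[:n_start_ok] >= query.start - maxgap
        return np.flatnonzero(mask)


def intervals_to_frame(intervals: Iterable[GenomicInterval]) -> pd.DataFrame:
    rows = [(iv.chrom, iv.start, iv.end, iv.strand) for iv in intervals]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])


def sort_key(iv: GenomicInterval) -> tuple:
    return (iv.chrom, iv.start, iv.end, iv.strand)
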
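"""Four-way chromatin classification of DNMT3C targets and peak overlaps.

Targets are partitioned by co-occupancy of H3K4me3 and H3K27me3 peaks:

* ``likely_bivalent``  — overlapped by >=1 peak from *both* marks,
* ``h3k4me3_marked``   — H3K4me3 peaks only,
* ``h3k27me3_marked``  — H3K27me3 peaks only,
* ``uncategorized``    — no peak from either mark.

Co-occupancy is judged at the target: a K4 peak and a K27 peak need not
overlap each other, only the target. The module also computes generic
peak/target overlap fractions with a maxgap (used for TF peaks such as
NRF1, where the convention is a 750 bp maxgap).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import pandas as pd

from .intervals import DNMT3CTarget, GenomicInterval, IntervalIndex

# re-exported convenience
from .intervals import overlaps_maxgap  # noqa: F401


class ChromatinCategory(str, Enum):
    LIKELY_BIVALENT = "likely_bivalent"
    H3K4ME3_MARKED = "h3k4me3_marked"
    H3K27ME3_MARKED = "h3k27me3_marked"
    UNCATEGORIZED = "uncategorized"


CATEGORY_ORDER = [
    ChromatinCategory.LIKELY_BIVALENT,
    ChromatinCategory.H3K4ME3_MARKED,
    ChromatinCategory.H3K27ME3_MARKED,
    ChromatinCategory.UNCATEGORIZED,
]


@dataclass
class PeakSet:
    """Called peaks for one mark in one condition (genotype x stage)."""

    mark: str
    peaks: Sequence[GenomicInterval]
    condition: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.mark:
            raise ValueError("mark must be non-empty")


def classify_targets(
    targets: Sequence[DNMT3CTarget],
    k4: PeakSet,
    k27: PeakSet,
    maxgap: int = 0,
    allow_condition_mismatch: bool = False,
) -> dict[str, ChromatinCategory]:
    """Assign each target exactly one chromatin category.

    ``maxgap`` follows the gap predicate (0 = overlap or touch). Peak sets
    must come from the same condition unless ``allow_condition_mismatch``.
    Returns a mapping keyed by the target's TE locus id.
    """
    if k4.mark == k27.mark:
        raise ValueError(f"both peak sets carry the same mark {k4.mark!r}")
    if (
        not allow_condition_mismatch
        and k4.condition
        and k27.condition
        and dict(k4.condition) != dict(k27.condition)
    ):
        raise ValueError(
            f"peak sets come from different conditions: {k4.condition} vs {k27.condition}"
        )
    k4_index = IntervalIndex(k4.peaks)
    k27_index = IntervalIndex(k27.peaks)
    assignment: dict[str, ChromatinCategory] = {}
    for t in targets:
        has_k4 = k4_index.any_overlap(t.interval, maxgap=maxgap)
        has_k27 = k27_index.any_overlap(t.interval, maxgap=maxgap)
        if has_k4 and has_k27:
            cat = ChromatinCategory.LIKELY_BIVALENT
        elif has_k4:
            cat = ChromatinCategory.H3K4ME3_MARKED
        elif has_k27:
            cat = ChromatinCategory.H3K27ME3_MARKED
        else:
            cat = ChromatinCategory.UNCATEGORIZED
        assignment[t.te.locus_id] = cat
    return assignment


def category_composition(
    assignment: Mapping[str, ChromatinCategory],
    targets: Sequence[DNMT3CTarget],
    by: str = "family",
) -> pd.DataFrame:
    """Percentage of TE families (or classes/subfamilies) per category.

    Long table with columns category, group, count, percent; percentages sum
    to 100 within each non-empty category.
    """
    if by not in {"family", "te_class", "subfamily"}:
        raise ValueError(f"unknown grouping {by!r}")
    missing = [t.te.locus_id for t in targets if t.te.locus_id not in assignment]
    if missing:
        raise ValueError(f"targets missing from assignment: {missing[:5]}")
    rows = []
    for t in targets:
        cat = assignment[t.te.locus_id]
        group = getattr(t.te, by)
        rows.append((cat.value, group))
    df = pd.DataFrame(rows, columns=["category", "group"])
    if df.empty:
        return pd.DataFrame(columns=["category", "group", "count", "percent"])
    counts = df.groupby(["category", "group"], sort=True).size().rename("count").reset_index()
    totals = counts.groupby("category")["count"].transform("sum")
    counts["percent"] = 100.0 * counts["count"] / totals
    return counts


def assignment_to_frame(assignment: Mapping[str, ChromatinCategory]) -> pd.DataFrame:
    return pd.DataFrame(
        sorted((k, v.value) for k, v in assignment.items()),
        columns=["target_id", "category"],
    )


def peak_target_overlap_fraction(
    peaks: PeakSet,
    targets: Sequence[DNMT3CTarget],
    maxgap: int = 750,
) -> tuple[float, float]:
    """(fraction of targets hit by >=1 peak, fraction of peaks hitting >=1 target).

    Each target and each peak counts once regardless of multiplicity.
    Empty inputs yield fraction 0 for that side.
    """
    if maxgap < 0:
        raise ValueError("maxgap must be >= 0")
    peak_index = IntervalIndex(peaks.peaks)
    target_index = IntervalIndex([t.interval for t in targets])
    n_targets_hit = sum(
        1 for t in targets if peak_index.any_overlap(t.interval, maxgap=maxgap)
    )
    n_peaks_hit = sum(
        1 for p in peaks.peaks if target_index.any_overlap(p, maxgap=maxgap)
    )
    frac_targets = n_targets_hit / len(targets) if targets else 0.0
    frac_peaks = n_peaks_hit / len(peaks.peaks) if peaks.peaks else 0.0
    return frac_targets, frac_peaks
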
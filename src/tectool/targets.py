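"""High-confidence TE sets and DNMT3C-target definition.

A DNMT3C target is a TE copy whose promoter lost DNA methylation in the
knockout: operationally, a copy overlapping at least one differentially
methylated region (DMR) by >=1 bp and passing a class-specific length
filter — LINE (L1) copies longer than 5 kb, LTR copies longer than 500 bp
("longer than" read strictly). Copies of other classes are excluded.

The "high-confidence" TE set removes copies that overlap annotated genes by
any amount, so that TE-assigned signal cannot be gene-derived; it is applied
by default to the motif-enrichment stage only.
"""

from __future__ import annotations

from typing import Sequence

from .intervals import (
    DMR,
    DNMT3CTarget,
    GenomicInterval,
    IntervalIndex,
    TECopy,
    sort_key,
)

MIN_LINE_LEN = 5000
MIN_LTR_LEN = 500


def build_high_confidence_te_set(
    tes: Sequence[TECopy], genes: Sequence[GenomicInterval]
) -> list[TECopy]:
    """TE copies with zero-bp overlap against any gene, canonically sorted."""
    index = IntervalIndex(genes)
    kept = [te for te in tes if not index.any_overlap(te.interval)]
    return sorted(kept, key=lambda te: sort_key(te.interval))


def passes_length_filter(
    te: TECopy, min_line_len: int = MIN_LINE_LEN, min_ltr_len: int = MIN_LTR_LEN
) -> bool:
    if te.te_class == "LINE":
        return te.length > min_line_len
    if te.te_class == "LTR":
        return te.length > min_ltr_len
    return False


def define_dnmt3c_targets(
    dmrs: Sequence[DMR],
    tes: Sequence[TECopy],
    min_line_len: int = MIN_LINE_LEN,
    min_ltr_len: int = MIN_LTR_LEN,
) -> list[DNMT3CTarget]:
    """Intersect DMRs with length-filtered TE copies.

    A copy hit by several DMRs yields one target; the supporting DMR names
    are recorded. Output is canonically sorted, so the operation is
    idempotent and order-independent.
    """
    dmr_index = IntervalIndex([d.interval for d in dmrs])
    dmrs_sorted_per_chrom: dict[str, list[DMR]] = {}
    # stable start-order per chromosome, mirroring IntervalIndex's internal order
    for d in sorted(dmrs, key=lambda d: (d.interval.chrom, d.interval.start)):
        dmrs_sorted_per_chrom.setdefault(d.interval.chrom, []).append(d)

    targets: list[DNMT3CTarget] = []
    for te in tes:
        if not passes_length_filter(te, min_line_len, min_ltr_len):
            continue
        idx = dmr_index.overlapping_indices(te.interval)
        if idx.size == 0:
            continue
        chrom_dmrs = dmrs_sorted_per_chrom[te.interval.chrom]
        names = tuple(chrom_dmrs[i].name for i in idx)
        targets.append(DNMT3CTarget(te, supporting_dmrs=names))
    return sorted(targets, key=lambda t: sort_key(t.interval))
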
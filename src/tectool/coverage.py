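"""Coverage tracks, RPGC normalization and target-centered profile matrices.

RPGC ("reads per genomic content") rescales a track so that the mean
per-base coverage over the effective genome equals 1x:
``factor = G / (n_fragments * mean_fragment_length)``.

Profile matrices follow the deepTools layout: one row per target, columns
are fixed-width bins across ``[-flank, +flank)`` around the target midpoint,
rows of minus-strand targets reversed when strand-aware (the default, since
TE promoter orientation matters). Multimapping fragments are placed at one
uniformly chosen candidate location, mirroring the random-assignment
convention used upstream of this package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .intervals import DNMT3CTarget, GenomicInterval

log = logging.getLogger(__name__)


@dataclass
class Fragment:
    """A sequenced fragment with one or more candidate genomic locations."""

    candidates: Sequence[GenomicInterval]

    def __post_init__(self) -> None:
        if len(self.candidates) == 0:
            raise ValueError("fragment with zero candidate locations")

    @property
    def is_unique(self) -> bool:
        return len(self.candidates) == 1


@dataclass
class CoverageTrack:
    """Per-chromosome per-base depth arrays."""

    depths: dict[str, np.ndarray]
    normalization: str = "raw"  # raw | RPGC
    binsize: int = 1

    def total_mass(self) -> float:
        return float(sum(arr.sum() for arr in self.depths.values()))

    def genome_size(self) -> int:
        return int(sum(arr.size for arr in self.depths.values()))

    def mean_coverage(self) -> float:
        g = self.genome_size()
        return self.total_mass() / g if g else 0.0


def assign_multimappers(fragments: Sequence[Fragment], seed: int) -> list[GenomicInterval]:
    """Resolve each fragment to one location, uniformly among candidates."""
    rng = np.random.default_rng(seed)
    placed: list[GenomicInterval] = []
    for frag in fragments:
        if frag.is_unique:
            placed.append(frag.candidates[0])
        else:
            placed.append(frag.candidates[rng.integers(len(frag.candidates))])
    return placed


def coverage_from_locations(
    locations: Sequence[GenomicInterval], chrom_sizes: dict[str, int]
) -> CoverageTrack:
    depths = {c: np.zeros(n, dtype=float) for c, n in chrom_sizes.items()}
    for iv in locations:
        arr = depths.get(iv.chrom)
        if arr is None:
            continue
        depths[iv.chrom][max(0, iv.start) : min(arr.size, iv.end)] += 1.0
    return CoverageTrack(depths)


def rpgc_scale_factor(
    n_fragments: int, mean_fragment_length: float, effective_genome_size: int
) -> float:
    if n_fragments <= 0:
        raise ValueError("n_fragments must be > 0")
    if mean_fragment_length <= 0 or effective_genome_size <= 0:
        raise ValueError("fragment length and genome size must be > 0")
    return effective_genome_size / (n_fragments * mean_fragment_length)


def rpgc_normalize(track: CoverageTrack, effective_genome_size: int | None = None) -> CoverageTrack:
    """Scale a raw track to 1x mean genome coverage."""
    g = effective_genome_size or track.genome_size()
    mass = track.total_mass()
    if mass == 0:
        raise ValueError("cannot RPGC-normalize an empty track")
    factor = g / mass
    return CoverageTrack(
        {c: arr * factor for c, arr in track.depths.items()},
        normalization="RPGC",
        binsize=track.binsize,
    )


@dataclass
class ProfileMatrix:
    matrix: np.ndarray  # targets x bins
    target_ids: list[str]
    flank: int
    binsize: int
    n_skipped: int = 0
    clipped_rows: list[int] = field(default_factory=list)

    @property
    def metaplot(self) -> np.ndarray:
        """Column means across targets (the metaplot line)."""
        if self.matrix.shape[0] == 0:
            return np.zeros(self.matrix.shape[1])
        return self.matrix.mean(axis=0)

    def ordered_by_mean(self) -> "ProfileMatrix":
        order = np.argsort(-self.matrix.mean(axis=1), kind="stable")
        return ProfileMatrix(
            self.matrix[order],
            [self.target_ids[i] for i in order],
            self.flank,
            self.binsize,
            self.n_skipped,
            self.clipped_rows,
        )


def profile_matrix(
    track: CoverageTrack,
    targets: Sequence[DNMT3CTarget],
    flank: int = 3000,
    binsize: int = 50,
    strand_aware: bool = True,
    anchor: str = "midpoint",
) -> ProfileMatrix:
    """Mean coverage per bin in ``[-flank, +flank)`` around each target.

    Bins beyond chromosome ends are filled with 0 and the row flagged as
    clipped; targets on chromosomes absent from the track are skipped and
    counted.
    """
    if flank % binsize != 0:
        raise ValueError("flank must be a multiple of binsize")
    if anchor not in {"midpoint", "five_prime"}:
        raise ValueError(f"unknown anchor {anchor!r}")
    n_bins = 2 * flank // binsize
    rows, ids, clipped = [], [], []
    n_skipped = 0
    for t in targets:
        iv = t.interval
        arr = track.depths.get(iv.chrom)
        if arr is None:
            log.warning("target %s on chromosome absent from track; skipped", t.te.locus_id)
            n_skipped += 1
            continue
        if anchor == "midpoint":
            center = iv.midpoint
        else:
            center = iv.start if iv.strand != "-" else iv.end
        lo, hi = center - flank, center + flank
        window = np.zeros(2 * flank, dtype=float)
        src_lo, src_hi = max(0, lo), min(arr.size, hi)
        if src_lo > lo or src_hi < hi:
            clipped.append(len(rows))
        if src_hi > src_lo:
            window[src_lo - lo : src_hi - lo] = arr[src_lo:src_hi]
        row = window.reshape(n_bins, binsize).mean(axis=1)
        if strand_aware and iv.strand == "-":
            row = row[::-1]
        rows.append(row)
        ids.append(t.te.locus_id)
    matrix = np.array(rows) if rows else np.zeros((0, n_bins))
    return ProfileMatrix(matrix, ids, flank, binsize, n_skipped, clipped)
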
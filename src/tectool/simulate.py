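"""Synthetic-data generator with planted ground truth.

Every input the pipeline consumes can be generated here: a small genome
with planted TE copies of named subfamilies, DMRs over a configurable
subset, peak sets realizing planted chromatin categories (with analytically
tractable dropout/spurious noise), negative-binomial locus counts with
planted stage/genotype fold changes, a planted NRF1-like GC-rich palindrome
in a subset of TE promoters, and log-normal pulldown intensities with
planted methylation-sensitive binders.

The defaults define the study conditions the pipeline is validated under:
two stages (Spg, Spc) x two genotypes (WT, KO) x 3 replicates, NB counts
with mean 200 and dispersion 0.1, knockout upregulation planted on the
young ERVK subfamilies and L1MdT/L1MdA, a meiotic (Spc) boost on L1, and
chromatin-category expression multipliers ordered
H3K4me3 > likely-bivalent > H3K27me3 > uncategorized. A fixed seed fully
determines every emitted file.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as tio
from .bait import PWM
from .chromatin import ChromatinCategory, PeakSet
from .coverage import CoverageTrack, Fragment
from .intervals import DMR, GenomicInterval, TECopy

NRF1_CORE = "GCGCATGCGC"  # GC-rich palindromic core motif

CATEGORY_MARKS = {
    ChromatinCategory.LIKELY_BIVALENT: ("H3K4me3", "H3K27me3"),
    ChromatinCategory.H3K4ME3_MARKED: ("H3K4me3",),
    ChromatinCategory.H3K27ME3_MARKED: ("H3K27me3",),
    ChromatinCategory.UNCATEGORIZED: (),
}


@dataclass
class SubfamilySpec:
    name: str
    family: str
    te_class: str
    length: int
    n_copies: int
    # probability of each planted chromatin category for target copies
    category_probs: dict[str, float]
    log2fc_ko: float = 0.0  # planted KO-vs-WT fold change (log2)
    log2fc_spc: float = 0.0  # planted Spc-vs-Spg boost (log2), both genotypes
    motif_rate: float = 0.0  # NRF1-motif insertion rate for DNMT3C-target copies


def _default_subfamilies() -> list[SubfamilySpec]:
    biv = {"likely_bivalent": 0.7, "h3k4me3_marked": 0.1,
           "h3k27me3_marked": 0.1, "uncategorized": 0.1}
    active = {"likely_bivalent": 0.1, "h3k4me3_marked": 0.7,
              "h3k27me3_marked": 0.1, "uncategorized": 0.1}
    repressed = {"likely_bivalent": 0.1, "h3k4me3_marked": 0.1,
                 "h3k27me3_marked": 0.6, "uncategorized": 0.2}
    uncat = {"likely_bivalent": 0.05, "h3k4me3_marked": 0.05,
             "h3k27me3_marked": 0.2, "uncategorized": 0.7}
    young = [
        SubfamilySpec("L1MdT", "L1", "LINE", 6500, 40, biv,
                      log2fc_ko=1.5, log2fc_spc=1.5, motif_rate=0.5),
        SubfamilySpec("L1MdA", "L1", "LINE", 6200, 40, repressed,
                      log2fc_ko=1.0, log2fc_spc=1.0, motif_rate=0.2),
        SubfamilySpec("L1MdF", "L1", "LINE", 4000, 20, repressed),  # fails >5 kb filter
        SubfamilySpec("IAPEz-int", "ERVK", "LTR", 3500, 40, active,
                      log2fc_ko=2.0, motif_rate=0.6),
        SubfamilySpec("IAPLTR1a", "ERVK", "LTR", 600, 40, active,
                      log2fc_ko=2.0, motif_rate=0.6),
        SubfamilySpec("MMERVK10C-int", "ERVK", "LTR", 5000, 40, active,
                      log2fc_ko=2.0, motif_rate=0.3),
    ]
    # ancient, transcriptionally inert families: the null majority that
    # anchors TMM normalization, as in a genome-wide repeat annotation
    ancient = [
        SubfamilySpec("Lx8", "L1", "LINE", 3000, 40, uncat),
        SubfamilySpec("L1M5", "L1", "LINE", 2800, 40, uncat),
        SubfamilySpec("MTA_Mm", "ERVL-MaLR", "LTR", 450, 40, uncat),
        SubfamilySpec("MTB", "ERVL-MaLR", "LTR", 400, 40, uncat),
        SubfamilySpec("MTC", "ERVL-MaLR", "LTR", 380, 40, uncat),
        SubfamilySpec("ORR1A0", "ERVL-MaLR", "LTR", 350, 40, uncat),
        SubfamilySpec("MLT1A0", "ERVL-MaLR", "LTR", 380, 40, uncat),
        SubfamilySpec("B1_Mm", "Alu", "SINE", 150, 40, uncat),
        SubfamilySpec("B2_Mm1a", "B2", "SINE", 190, 40, uncat),
        SubfamilySpec("B4A", "B4", "SINE", 150, 40, uncat),
        SubfamilySpec("MIRb", "MIR", "SINE", 200, 40, uncat),
        SubfamilySpec("PB1D10", "Alu", "SINE", 120, 40, uncat),
    ]
    return young + ancient


@dataclass
class PlantedBinder:
    protein: str
    sequence_specific: bool
    methyl_sensitive: bool
    effect: float = 8.0  # fold change on the elevated conditions


@dataclass
class SimulationConfig:
    seed: int = 0
    genome_length: int = 7_000_000
    n_chromosomes: int = 2
    gc_content: float = 0.42
    subfamilies: list[SubfamilySpec] = field(default_factory=_default_subfamilies)
    divergence: float = 0.05  # per-base substitution from consensus
    promoter_length: int = 250
    dmr_fraction: float = 0.8
    gene_overlap_fraction: float = 0.1  # TE copies deliberately placed in genes
    n_genes: int = 30
    gene_length: int = 2000
    peak_dropout: float = 0.0
    peak_spurious: float = 0.0
    peak_halfwidth: int = 500
    motif_background_rate: float = 0.05  # NRF1-motif rate for non-target copies
    nb_mean: float = 200.0
    nb_dispersion: float = 0.1
    locus_lognormal_sd: float = 0.3  # per-locus baseline variability
    # biological replicate variability shared by all loci of a subfamily in
    # one sample; this is what keeps subfamily-aggregated counts overdispersed
    sample_lognormal_sd: float = 0.2
    wt_silencing_factor: float = 1.0  # WT baseline multiplier (FC planted on KO)
    category_multipliers: dict[str, float] = field(
        default_factory=lambda: {
            "h3k4me3_marked": 6.0,
            "likely_bivalent": 2.5,
            "h3k27me3_marked": 0.5,
            "uncategorized": 0.3,
        }
    )
    stages: tuple[str, ...] = ("Spg", "Spc")
    genotypes: tuple[str, ...] = ("WT", "KO")
    replicates: int = 3
    n_proteins: int = 300
    pulldown_effect: float = 8.0
    pulldown_noise_sd: float = 0.3
    planted_binders: list[PlantedBinder] = field(
        default_factory=lambda: [
            PlantedBinder("NRF1", sequence_specific=True, methyl_sensitive=True),
            PlantedBinder("CREB1", sequence_specific=False, methyl_sensitive=True),
        ]
    )

    def validate(self) -> None:
        for name, value in [
            ("divergence", self.divergence),
            ("dmr_fraction", self.dmr_fraction),
            ("gene_overlap_fraction", self.gene_overlap_fraction),
            ("peak_dropout", self.peak_dropout),
            ("peak_spurious", self.peak_spurious),
            ("gc_content", self.gc_content),
        ]:
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates per condition")
        for spec in self.subfamilies:
            total = sum(spec.category_probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"category probabilities for {spec.name} sum to {total}, not 1"
                )


@dataclass
class SimulatedGenome:
    genome: dict[str, str]
    te_copies: list[TECopy]
    genes: list[GenomicInterval]
    dmrs: list[DMR]
    planted_categories: dict[str, str]  # locus_id -> category (targets only)
    motif_copies: set[str]  # locus_ids carrying an intact NRF1 motif
    consensus: dict[str, str]  # subfamily -> consensus sequence

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=probs)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    bases = "ACGT"
    for i in hits:
        alternatives = bases.replace(chars[i], "")
        chars[i] = alternatives[rng.integers(3)]
    return "".join(chars)


def simulate_genome(config: SimulationConfig) -> SimulatedGenome:
    """Plant TE copies, genes and DMRs on a random genome.

    Placement uses fixed-pitch slots (one feature per slot, generous
    margins) so features never collide and peak windows stay separable.
    DMRs cover a ``dmr_fraction`` subset of the copies (count rounded to
    nearest integer), anchored on each copy's 5' promoter.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    max_len = max(
        [s.length for s in config.subfamilies] + [config.gene_length] or [0]
    )
    slot = max_len + 2500  # flank margin: peak windows stay separable
    n_te = sum(s.n_copies for s in config.subfamilies)
    n_needed = n_te + config.n_genes
    per_chrom = config.genome_length // config.n_chromosomes
    n_slots = (per_chrom // slot) * config.n_chromosomes
    if n_slots < n_needed:
        raise ValueError(
            f"genome too short: {n_needed} features need "
            f"{n_needed * slot} bp but only {n_slots * slot} bp of slots fit "
            f"(shortfall {(n_needed - n_slots) * slot} bp)"
        )

    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    genome_arrays = {
        c: list(_random_seq(rng, per_chrom, config.gc_content)) for c in chroms
    }

    slots = [
        (c, i * slot) for c in chroms for i in range(per_chrom // slot)
    ]
    order = rng.permutation(len(slots))
    slot_iter = iter(order)

    consensus: dict[str, str] = {}
    for spec in config.subfamilies:
        seq = _random_seq(rng, spec.length, config.gc_content + 0.05)
        consensus[spec.name] = seq

    # genes first so TE copies can be placed inside some of them
    genes: list[GenomicInterval] = []
    for _ in range(config.n_genes):
        c, pos = slots[next(slot_iter)]
        start = pos + 1000
        genes.append(GenomicInterval(c, start, start + config.gene_length, "+"))
    genes.sort()

    te_copies: list[TECopy] = []
    motif_copies: set[str] = set()
    gene_pool = list(genes)
    rng.shuffle(gene_pool)  # type: ignore[arg-type]
    gene_iter = iter(gene_pool)

    for spec in config.subfamilies:
        n_in_genes = int(round(config.gene_overlap_fraction * spec.n_copies))
        for i in range(spec.n_copies):
            strand = "+" if rng.random() < 0.5 else "-"
            seq = _mutate(rng, consensus[spec.name], config.divergence)
            placed_in_gene = False
            if i < n_in_genes:
                gene = next(gene_iter, None)
                if gene is not None and gene.length >= 1:
                    start = max(0, gene.start - spec.length // 2)
                    placed_in_gene = True
            if not placed_in_gene:
                try:
                    c, pos = slots[next(slot_iter)]
                except StopIteration as exc:  # pragma: no cover - sized above
                    raise ValueError("ran out of placement slots") from exc
                start = pos + 1500
            else:
                c = gene.chrom
            end = start + spec.length
            genomic = seq if strand == "+" else _revcomp(seq)
            genome_arrays[c][start:end] = list(genomic)
            te_copies.append(
                TECopy(GenomicInterval(c, start, end, strand),
                       spec.name, spec.family, spec.te_class)
            )

    te_copies.sort(key=lambda t: (t.interval.chrom, t.interval.start))

    # DMRs over a rounded fraction of copies, anchored on the 5' promoter
    n_dmr = int(round(config.dmr_fraction * len(te_copies)))
    dmr_idx = sorted(rng.choice(len(te_copies), size=n_dmr, replace=False))
    dmrs: list[DMR] = []
    for j, idx in enumerate(dmr_idx):
        iv = te_copies[idx].interval
        if iv.strand == "-":
            lo, hi = max(0, iv.end - 400), iv.end + 100
        else:
            lo, hi = max(0, iv.start - 100), iv.start + 400
        dmrs.append(DMR(GenomicInterval(iv.chrom, lo, hi), name=f"dmr_{j}"))

    # planted categories for copies that will satisfy the target definition
    from .targets import define_dnmt3c_targets  # local import avoids a cycle

    targets = define_dnmt3c_targets(dmrs, te_copies)
    spec_by_name = {s.name: s for s in config.subfamilies}
    planted: dict[str, str] = {}
    labels = [c.value for c in ChromatinCategory]
    for t in targets:
        probs = spec_by_name[t.te.subfamily].category_probs
        p = np.array([probs.get(lbl, 0.0) for lbl in labels])
        planted[t.te.locus_id] = labels[rng.choice(len(labels), p=p / p.sum())]

    # plant the NRF1-like motif in the promoter window: target copies at the
    # subfamily's target rate, all other copies at the background rate
    target_ids = {t.te.locus_id for t in targets}
    mlen = len(NRF1_CORE)
    for te in te_copies:
        rate = (
            spec_by_name[te.subfamily].motif_rate
            if te.locus_id in target_ids
            else config.motif_background_rate
        )
        if rng.random() >= rate:
            continue
        iv = te.interval
        mpos = min(100, max(0, te.length - mlen))  # inside the 5' promoter
        if iv.strand == "-":
            g_lo = iv.end - mpos - mlen
            insert = _revcomp(NRF1_CORE)
        else:
            g_lo = iv.start + mpos
            insert = NRF1_CORE
        genome_arrays[iv.chrom][g_lo : g_lo + mlen] = list(insert)
        motif_copies.add(te.locus_id)

    genome = {c: "".join(arr) for c, arr in genome_arrays.items()}
    return SimulatedGenome(genome, te_copies, genes, dmrs, planted,
                           motif_copies, consensus)


# ---------------------------------------------------------------- peaks


def simulate_peaks(
    targets: Sequence[TECopy],
    planted_categories: Mapping[str, str],
    peak_dropout: float,
    peak_spurious: float,
    seed: int,
    halfwidth: int = 500,
    condition: Mapping[str, str] | None = None,
) -> dict[str, PeakSet]:
    """Emit H3K4me3/H3K27me3 peak sets realizing the planted categories.

    Per mark and target independently: an intended peak is dropped with
    probability ``peak_dropout``; an unintended peak appears with
    probability ``peak_spurious``.
    """
    valid = {c.value for c in ChromatinCategory}
    rng = np.random.default_rng(seed)
    condition = dict(condition or {"genotype": "KO", "stage": "Spg"})
    peaks: dict[str, list[GenomicInterval]] = {"H3K4me3": [], "H3K27me3": []}
    for te in targets:
        label = planted_categories.get(te.locus_id)
        if label is None:
            continue
        if label not in valid:
            raise ValueError(f"unknown planted category {label!r}")
        intended = CATEGORY_MARKS[ChromatinCategory(label)]
        center = te.interval.midpoint
        for mark in peaks:
            if mark in intended:
                emit = rng.random() >= peak_dropout
            else:
                emit = rng.random() < peak_spurious
            if emit:
                lo = max(0, center - halfwidth)
                peaks[mark].append(GenomicInterval(te.interval.chrom, lo, center + halfwidth))
    return {
        mark: PeakSet(mark=mark, peaks=sorted(ivs), condition=condition)
        for mark, ivs in peaks.items()
    }


def expected_recovery_accuracy(
    category_counts: Mapping[str, int], dropout: float, spurious: float
) -> float:
    """Exact expected fraction of correctly re-classified planted targets.

    Per mark, an intended peak survives with probability 1-dropout and an
    unintended one stays absent with probability 1-spurious; a target is
    recovered iff both marks are observed as planted.
    """
    total = sum(category_counts.values())
    if total == 0:
        return 1.0
    acc = 0.0
    for label, n in category_counts.items():
        intended = CATEGORY_MARKS[ChromatinCategory(label)]
        p = 1.0
        for mark in ("H3K4me3", "H3K27me3"):
            p *= (1 - dropout) if mark in intended else (1 - spurious)
        acc += n * p
    return acc / total


# ---------------------------------------------------------------- counts


def make_design(
    stages: Sequence[str] = ("Spg", "Spc"),
    genotypes: Sequence[str] = ("WT", "KO"),
    replicates: int = 3,
) -> pd.DataFrame:
    rows = [
        {
            "sample": f"{g}_{s}_rep{r + 1}",
            "stage": s,
            "genotype": g,
            "replicate": r + 1,
        }
        for s in stages
        for g in genotypes
        for r in range(replicates)
    ]
    return pd.DataFrame(rows)


def simulate_counts(
    te_copies: Sequence[TECopy],
    design: pd.DataFrame,
    nb_mean: float,
    nb_dispersion: float,
    planted_log2fc: Mapping[str, float],
    seed: int,
    stage_log2fc: Mapping[str, float] | None = None,
    boosted_stage: str = "Spc",
    ko_genotype: str = "KO",
    category_assignment: Mapping[str, str] | None = None,
    category_multipliers: Mapping[str, float] | None = None,
    locus_lognormal_sd: float = 0.0,
    sample_lognormal_sd: float = 0.0,
) -> pd.DataFrame:
    """Negative-binomial locus counts with planted genotype/stage effects.

    Per locus l and sample s the expected count is
    ``nb_mean * base_l * 2^(log2fc[subfam] * [genotype==KO])
    * 2^(stage_log2fc[subfam] * [stage==boosted])``, with ``base_l`` a
    per-locus log-normal factor times an optional chromatin-category
    multiplier. Variance is ``mu + dispersion * mu^2`` per locus;
    ``sample_lognormal_sd`` adds a mean-one log-normal factor shared by all
    loci of a subfamily within one sample (biological replicate
    variability that survives subfamily aggregation).
    """
    if nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be > 0")
    rng = np.random.default_rng(seed)
    stage_log2fc = stage_log2fc or {}
    category_multipliers = category_multipliers or {}
    category_assignment = category_assignment or {}

    locus_ids = [te.locus_id for te in te_copies]
    base = np.exp(rng.normal(0.0, locus_lognormal_sd, size=len(te_copies)))
    for i, te in enumerate(te_copies):
        cat = category_assignment.get(te.locus_id)
        if cat is not None:
            base[i] *= category_multipliers.get(cat, 1.0)

    r = 1.0 / nb_dispersion
    subfams = sorted({te.subfamily for te in te_copies})
    data = {}
    for _, row in design.iterrows():
        bio = {
            sf: np.exp(rng.normal(-0.5 * sample_lognormal_sd**2, sample_lognormal_sd))
            if sample_lognormal_sd > 0
            else 1.0
            for sf in subfams
        }
        mu = nb_mean * base.copy()
        for i, te in enumerate(te_copies):
            fc = 0.0
            if row["genotype"] == ko_genotype:
                fc += planted_log2fc.get(te.subfamily, 0.0)
            if row["stage"] == boosted_stage:
                fc += stage_log2fc.get(te.subfamily, 0.0)
            mu[i] *= bio[te.subfamily] * 2.0 ** fc
        p = r / (r + mu)
        data[row["sample"]] = rng.negative_binomial(r, p)
    return pd.DataFrame(data, index=pd.Index(locus_ids, name="locus"))


# ---------------------------------------------------------------- coverage


def simulate_coverage_fragments(
    genome: SimulatedGenome,
    mark: str,
    seed: int,
    n_background: int = 20_000,
    fragments_per_peak: int = 60,
    fragment_length: int = 200,
    multimap_fraction: float = 0.2,
) -> list[Fragment]:
    """Fragments enriched at targets whose planted category carries ``mark``.

    A ``multimap_fraction`` of enriched fragments receives a second
    candidate location inside another copy of the same subfamily, to
    exercise random multimapper assignment.
    """
    rng = np.random.default_rng(seed)
    sizes = genome.chrom_sizes
    chroms = list(sizes)
    copies_by_subfam: dict[str, list[TECopy]] = {}
    for te in genome.te_copies:
        copies_by_subfam.setdefault(te.subfamily, []).append(te)
    by_id = {te.locus_id: te for te in genome.te_copies}

    fragments: list[Fragment] = []
    for _ in range(n_background):
        c = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, sizes[c] - fragment_length))
        fragments.append(Fragment([GenomicInterval(c, start, start + fragment_length)]))

    for locus_id, label in genome.planted_categories.items():
        if mark not in CATEGORY_MARKS[ChromatinCategory(label)]:
            continue
        te = by_id[locus_id]
        center = te.interval.midpoint
        for _ in range(fragments_per_peak):
            offset = int(rng.normal(0, 150))
            start = max(0, center + offset - fragment_length // 2)
            primary = GenomicInterval(te.interval.chrom, start, start + fragment_length)
            candidates = [primary]
            mates = copies_by_subfam[te.subfamily]
            if len(mates) > 1 and rng.random() < multimap_fraction:
                other = mates[rng.integers(len(mates))]
                rel = int(rng.integers(0, max(1, other.length - fragment_length)))
                o_start = other.interval.start + rel
                candidates.append(
                    GenomicInterval(other.interval.chrom, o_start,
                                    o_start + fragment_length)
                )
            fragments.append(Fragment(candidates))
    return fragments


# ---------------------------------------------------------------- pulldown


def simulate_pulldown(
    protein_universe: Sequence[str],
    planted_binders: Sequence[PlantedBinder],
    replicates: int,
    seed: int,
    base_log2_mean: float = 20.0,
    protein_sd: float = 2.0,
    noise_sd: float = 0.3,
) -> dict[str, pd.DataFrame]:
    """Log-normal intensity tables for the four pulldown conditions.

    A binder's intensity is elevated by its effect on: the unmethylated
    bait always; the methylated bait if methylation-insensitive; the
    scrambled controls if sequence-unspecific (again respecting its
    methylation sensitivity).
    """
    if replicates < 2:
        raise ValueError("need >= 2 replicates per condition (Welch test undefined)")
    rng = np.random.default_rng(seed)
    proteins = list(protein_universe)
    planted = {b.protein: b for b in planted_binders}
    unknown = set(planted) - set(proteins)
    if unknown:
        raise ValueError(f"planted binders not in protein universe: {sorted(unknown)}")
    base = rng.normal(base_log2_mean, protein_sd, size=len(proteins))

    conditions = [
        "bait_unmethylated",
        "bait_methylated",
        "scrambled_unmethylated",
        "scrambled_methylated",
    ]

    def elevated(binder: PlantedBinder, cond: str) -> bool:
        scrambled = cond.startswith("scrambled")
        methylated = cond.endswith("_methylated") and "unmethylated" not in cond
        if scrambled and binder.sequence_specific:
            return False
        if methylated and binder.methyl_sensitive:
            return False
        return True

    out: dict[str, pd.DataFrame] = {}
    for cond in conditions:
        shift = np.zeros(len(proteins))
        for i, prot in enumerate(proteins):
            b = planted.get(prot)
            if b is not None and elevated(b, cond):
                shift[i] = np.log2(b.effect)
        cols = {}
        for r in range(replicates):
            log2_int = base + shift + rng.normal(0, noise_sd, size=len(proteins))
            cols[f"rep{r + 1}"] = 2.0 ** log2_int
        out[cond] = pd.DataFrame(cols, index=pd.Index(proteins, name="protein"))
    return out


# ---------------------------------------------------------------- motifs


def nrf1_pwm(certainty: float = 0.97) -> PWM:
    """Near-consensus PWM for the GC-rich palindromic NRF1-like core."""
    width = len(NRF1_CORE)
    mat = np.full((width, 4), (1 - certainty) / 3)
    for i, b in enumerate(NRF1_CORE):
        mat[i, "ACGT".index(b)] = certainty
    return PWM(name="NRF1_synthetic", matrix=mat)


def decoy_pwms(n: int, seed: int, width: int = 10, certainty: float = 0.97) -> list[PWM]:
    """Random near-consensus PWMs that should show no enrichment."""
    rng = np.random.default_rng(seed)
    pwms = []
    for k in range(n):
        cons = "".join("ACGT"[i] for i in rng.integers(0, 4, size=width))
        mat = np.full((width, 4), (1 - certainty) / 3)
        for i, b in enumerate(cons):
            mat[i, "ACGT".index(b)] = certainty
        pwms.append(PWM(name=f"DECOY{k + 1}_{cons}", matrix=mat))
    return pwms


def extract_te_sequences(
    genome: SimulatedGenome,
    copies: Sequence[TECopy],
    promoter_only: bool = False,
    promoter_length: int = 250,
) -> dict[str, str]:
    """Strand-oriented TE (or promoter-window) sequences keyed by locus id."""
    out = {}
    for te in copies:
        iv = te.interval
        seq = genome.genome[iv.chrom][iv.start : iv.end]
        if iv.strand == "-":
            seq = _revcomp(seq)
        if promoter_only:
            seq = seq[:promoter_length]
        out[te.locus_id] = seq
    return out


# ---------------------------------------------------------------- emission


def lengths_series(te_copies: Sequence[TECopy]) -> pd.Series:
    return pd.Series(
        {te.locus_id: te.length for te in te_copies}, name="length"
    )


def emit_all(
    config: SimulationConfig,
    outdir: str | Path,
    sim: SimulatedGenome | None = None,
) -> dict[str, Path]:
    """Generate every pipeline input under ``outdir``; returns the paths.

    ``sim`` may pass a genome already produced by :func:`simulate_genome`
    with this config (pure reuse; the output is identical either way).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if sim is None:
        sim = simulate_genome(config)
    paths: dict[str, Path] = {}

    paths["genome"] = outdir / "genome.fa"
    tio.write_fasta(paths["genome"], sim.genome)
    paths["te"] = outdir / "te_annotation.bed"
    tio.write_te_bed(paths["te"], sim.te_copies)
    paths["genes"] = outdir / "genes.bed"
    tio.write_bed_intervals(paths["genes"], sim.genes)
    paths["dmr"] = outdir / "dmrs.bed"
    with open(paths["dmr"], "w") as fh:
        for d in sim.dmrs:
            fh.write(f"{d.interval.chrom}\t{d.interval.start}\t{d.interval.end}\n")

    peak_sets = simulate_peaks(
        [te for te in sim.te_copies if te.locus_id in sim.planted_categories],
        sim.planted_categories,
        config.peak_dropout,
        config.peak_spurious,
        seed=config.seed + 1,
        halfwidth=config.peak_halfwidth,
    )
    for mark, ps in peak_sets.items():
        p = outdir / f"peaks_{mark}_KO_Spg.bed"
        tio.write_bed_intervals(p, ps.peaks)
        paths[f"peaks_{mark}"] = p

    design = make_design(config.stages, config.genotypes, config.replicates)
    paths["samples"] = outdir / "samples.tsv"
    tio.write_sample_sheet(paths["samples"], design)
    spec_by_name = {s.name: s for s in config.subfamilies}
    counts = simulate_counts(
        sim.te_copies,
        design,
        config.nb_mean,
        config.nb_dispersion,
        {s.name: s.log2fc_ko for s in config.subfamilies},
        seed=config.seed + 2,
        stage_log2fc={s.name: s.log2fc_spc for s in config.subfamilies},
        category_assignment=sim.planted_categories,
        category_multipliers=config.category_multipliers,
        locus_lognormal_sd=config.locus_lognormal_sd,
        sample_lognormal_sd=config.sample_lognormal_sd,
    )
    paths["counts"] = outdir / "te_counts.tsv"
    tio.write_counts(paths["counts"], counts)
    paths["lengths"] = outdir / "te_lengths.tsv"
    lengths_series(sim.te_copies).to_csv(paths["lengths"], sep="\t")

    motifs = [nrf1_pwm()] + decoy_pwms(3, seed=config.seed + 3)
    paths["motifs"] = outdir / "motifs.meme"
    tio.write_meme(paths["motifs"], motifs)

    proteins = [f"PROT{i:04d}" for i in range(config.n_proteins)]
    for b in config.planted_binders:
        if b.protein not in proteins:
            proteins[hash(b.protein) % len(proteins)] = b.protein
    tables = simulate_pulldown(
        proteins,
        config.planted_binders,
        config.replicates,
        seed=config.seed + 4,
        noise_sd=config.pulldown_noise_sd,
    )
    for cond, df in tables.items():
        p = outdir / f"pulldown_{cond}.tsv"
        df.to_csv(p, sep="\t")
        paths[f"pulldown_{cond}"] = p

    truth = {
        "planted_categories": sim.planted_categories,
        "motif_copies": sorted(sim.motif_copies),
        "planted_log2fc_ko": {s.name: s.log2fc_ko for s in config.subfamilies},
        "planted_binders": [dataclasses.asdict(b) for b in config.planted_binders],
        "seed": config.seed,
    }
    paths["truth"] = outdir / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return paths
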
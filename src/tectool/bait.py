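"""Methylation-sensitive TF discovery: baits, pulldown statistics, motifs.

Scrambled control baits preserve length, base composition and the exact
positions of every CpG dinucleotide of a promoter while uniformly shuffling
all other positions — so sequence-specific binding is destroyed but
CpG-directed (methylation-dependent) binding is not.

Pulldown enrichment compares log2 protein intensities between conditions
with Welch's t test. A protein is called ``methyl_sensitive`` when enriched
on the unmethylated vs methylated bait, and ``sequence_specific`` when
additionally NOT enriched on the matching scrambled-control contrast.

Motif analysis scans position weight matrices (log-odds, both strands) and
tests target-vs-background hit frequencies with a one-sided Fisher exact
test, BH-adjusted across motifs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .diffenrich import benjamini_hochberg

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = str.maketrans("ACGT", "TGCA")


def cpg_positions(seq: str) -> list[int]:
    """0-based indices i where seq[i:i+2] == 'CG'."""
    return [i for i in range(len(seq) - 1) if seq[i : i + 2] == "CG"]


@dataclass(frozen=True)
class BaitSequence:
    name: str
    sequence: str
    methylated: bool = False
    methylation_records: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if set(self.sequence) - set(BASES):
            bad = sorted(set(self.sequence) - set(BASES))
            raise ValueError(f"bait {self.name}: non-ACGT characters {bad}")

    @property
    def cpg_positions(self) -> list[int]:
        return cpg_positions(self.sequence)


def scramble_preserving_cpg(seq: str, seed: int, max_retries: int = 50) -> str:
    """Shuffle a sequence while pinning every CpG dinucleotide in place.

    Length, base composition and the exact CpG position set are preserved;
    the non-CpG positions receive a uniform random permutation of the
    remaining bases. Because the pinned C/G of a true CpG can never seed a
    new CpG with a neighbour, spurious CpGs arise only between two adjacent
    shuffled positions; each is repaired by swapping one member with a
    random other shuffled position (composition unchanged), with a bounded
    budget of whole-shuffle retries before giving up.
    """
    seq = seq.upper()
    if set(seq) - set(BASES):
        raise ValueError("sequence must be over ACGT")
    wanted = cpg_positions(seq)
    fixed = set()
    for i in wanted:
        fixed.add(i)
        fixed.add(i + 1)
    free = [i for i in range(len(seq)) if i not in fixed]
    pool = [seq[i] for i in free]
    rng = np.random.default_rng(seed)
    chars = list(seq)
    for _ in range(max_retries):
        perm = rng.permutation(len(pool))
        for slot, j in zip(free, perm):
            chars[slot] = pool[j]
        if _repair_spurious_cpgs(chars, wanted, free, rng):
            out = "".join(chars)
            if cpg_positions(out) == wanted:  # defensive re-check
                return out
    raise RuntimeError(
        "CpG-preserving shuffle failed within retry budget "
        "(pathological composition); consider a relaxed constraint"
    )


def _repair_spurious_cpgs(
    chars: list[str], wanted: list[int], free: list[int], rng: np.random.Generator
) -> bool:
    wanted_set = set(wanted)
    for _ in range(20 * max(len(chars), 1)):
        bad = [
            i
            for i in range(len(chars) - 1)
            if chars[i] == "C" and chars[i + 1] == "G" and i not in wanted_set
        ]
        if not bad:
            return True
        i = bad[rng.integers(len(bad))]
        victim = i if rng.random() < 0.5 else i + 1
        j = free[rng.integers(len(free))]
        chars[victim], chars[j] = chars[j], chars[victim]
    return False


def methylate_in_silico(bait: BaitSequence) -> BaitSequence:
    """Mark every CpG as fully methylated; sequence unchanged; idempotent."""
    if bait.methylated:
        warnings.warn(f"bait {bait.name} already methylated; no-op", stacklevel=2)
        return bait
    records = tuple(1.0 for _ in bait.cpg_positions)
    return replace(bait, methylated=True, methylation_records=records)


# ---------------------------------------------------------------- pulldown


@dataclass
class EnrichmentCall:
    protein: str
    log2fc_bait: float
    p_bait: float
    log2fc_scrambled: float
    p_scrambled: float
    sequence_specific: bool
    methyl_sensitive: bool
    skipped_reason: str = ""


def _welch_contrast(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """log2FC (mean difference of log2 intensities) and Welch two-sided p."""
    lfc = float(np.mean(a) - np.mean(b))
    _, p = stats.ttest_ind(a, b, equal_var=False)
    return lfc, float(p)


def pulldown_enrichment(
    tables: dict[str, pd.DataFrame],
    lfc_threshold: float = 1.0,
    p_threshold: float = 0.05,
    already_log: bool = False,
) -> list[EnrichmentCall]:
    """Classify proteins from the four pulldown tables.

    ``tables`` keys: ``bait_unmethylated``, ``bait_methylated``,
    ``scrambled_unmethylated``, ``scrambled_methylated``; each protein x
    replicate intensities. Proteins with <2 finite replicates in any
    condition are skipped with a reason.
    """
    required = {
        "bait_unmethylated",
        "bait_methylated",
        "scrambled_unmethylated",
        "scrambled_methylated",
    }
    missing = required - set(tables)
    if missing:
        raise ValueError(f"missing pulldown conditions: {sorted(missing)}")
    proteins = tables["bait_unmethylated"].index
    calls: list[EnrichmentCall] = []
    for prot in proteins:
        vals = {}
        short = None
        for cond in required:
            row = tables[cond].loc[prot].to_numpy(dtype=float)
            row = row[np.isfinite(row)]
            if row.size < 2:
                short = cond
                break
            vals[cond] = row if already_log else np.log2(np.maximum(row, 1.0))
        if short is not None:
            calls.append(
                EnrichmentCall(prot, np.nan, np.nan, np.nan, np.nan, False, False,
                               skipped_reason=f"<2 finite replicates in {short}")
            )
            continue
        lfc_b, p_b = _welch_contrast(vals["bait_unmethylated"], vals["bait_methylated"])
        lfc_s, p_s = _welch_contrast(
            vals["scrambled_unmethylated"], vals["scrambled_methylated"]
        )
        enriched_bait = lfc_b >= lfc_threshold and p_b < p_threshold
        enriched_scr = lfc_s >= lfc_threshold and p_s < p_threshold
        calls.append(
            EnrichmentCall(
                protein=prot,
                log2fc_bait=lfc_b,
                p_bait=p_b,
                log2fc_scrambled=lfc_s,
                p_scrambled=p_s,
                sequence_specific=enriched_bait and not enriched_scr,
                methyl_sensitive=enriched_bait,
            )
        )
    return calls


def enrichment_frame(calls: list[EnrichmentCall]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in calls]).set_index("protein")


# ---------------------------------------------------------------- motifs


@dataclass
class PWM:
    """Per-position base probabilities with a scanning background."""

    name: str
    matrix: np.ndarray  # width x 4, rows sum to 1
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    threshold_fraction: float = 0.8  # of the maximum achievable log-odds

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be width x 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"PWM {self.name}: rows must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self, pseudocount: float = 1e-3) -> np.ndarray:
        p = self.matrix + pseudocount
        p /= p.sum(axis=1, keepdims=True)
        bg = self.background + pseudocount
        bg /= bg.sum()
        return np.log2(p / bg)

    def default_threshold(self) -> float:
        lo = self.log_odds()
        return self.threshold_fraction * float(lo.max(axis=1).sum())


@dataclass(frozen=True)
class MotifHit:
    position: int
    strand: str
    score: float


def _encode(seq: str) -> np.ndarray:
    """Map to 0..3; non-ACGT positions become -1 (scored as background)."""
    out = np.full(len(seq), -1, dtype=np.int8)
    for i, c in enumerate(seq.upper()):
        out[i] = BASE_INDEX.get(c, -1)
    return out


def scan_pwm(seq: str, pwm: PWM, threshold: float | None = None) -> list[MotifHit]:
    """Log-odds scan of both strands; hits where score >= threshold.

    Positions are 0-based starts on the forward sequence for both strands.
    Non-ACGT characters contribute log-odds 0 (background).
    """
    if len(seq) < pwm.width:
        return []
    thr = pwm.default_threshold() if threshold is None else threshold
    lo = pwm.log_odds()
    lo_rc = lo[::-1, ::-1]  # reverse-complement log-odds
    enc = _encode(seq)
    w = pwm.width
    n = len(seq) - w + 1
    fwd = np.zeros(n)
    rev = np.zeros(n)
    for j in range(w):  # w column adds instead of an n*w python loop
        col = enc[j : j + n]
        valid = col >= 0
        fwd[valid] += lo[j, col[valid]]
        rev[valid] += lo_rc[j, col[valid]]
    hits: list[MotifHit] = []
    for start in range(n):
        if fwd[start] >= thr:
            hits.append(MotifHit(start, "+", float(fwd[start])))
        if rev[start] >= thr:
            hits.append(MotifHit(start, "-", float(rev[start])))
    return hits


def motif_enrichment(
    target_seqs: dict[str, str],
    background_seqs: dict[str, str],
    pwms: list[PWM],
    threshold: float | None = None,
) -> pd.DataFrame:
    """Per-motif target-vs-background enrichment of sequences with >=1 hit.

    One-sided Fisher exact test (enrichment in targets), BH across motifs.
    A motif absent everywhere reports odds ratio NA and p = 1.
    """
    if not target_seqs or not background_seqs:
        raise ValueError("target and background sets must be non-empty")
    rows = []
    for pwm in pwms:
        t_hit = sum(1 for s in target_seqs.values() if scan_pwm(s, pwm, threshold))
        b_hit = sum(1 for s in background_seqs.values() if scan_pwm(s, pwm, threshold))
        t_tot, b_tot = len(target_seqs), len(background_seqs)
        table = [[t_hit, t_tot - t_hit], [b_hit, b_tot - b_hit]]
        if t_hit == 0 and b_hit == 0:
            odds, p = np.nan, 1.0
        else:
            odds, p = stats.fisher_exact(table, alternative="greater")
            odds = float(odds) if np.isfinite(odds) else np.nan
        rows.append(
            {
                "motif": pwm.name,
                "targets_with_hit": t_hit,
                "targets_total": t_tot,
                "background_with_hit": b_hit,
                "background_total": b_tot,
                "odds_ratio": odds,
                "p_value": float(p),
            }
        )
    df = pd.DataFrame(rows).set_index("motif")
    df["padj"] = benjamini_hochberg(df["p_value"].to_numpy())
    return df
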
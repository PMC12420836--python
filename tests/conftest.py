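import numpy as np
import pytest

from tectool.intervals import DMR, DNMT3CTarget, GenomicInterval, TECopy


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=100_000, max_len=2000):
    out = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        strand = "+-."[rng.integers(3)]
        out.append(GenomicInterval(chrom, start, start + length, strand))
    return out


def random_te_copies(rng, n, **kwargs):
    subfams = [
        ("L1MdT", "L1", "LINE"),
        ("L1MdA", "L1", "LINE"),
        ("IAPLTR1a", "ERVK", "LTR"),
        ("MMERVK10C-int", "ERVK", "LTR"),
        ("B1_Mm", "Alu", "SINE"),
    ]
    ivs = random_intervals(rng, n, **kwargs)
    out = []
    for iv in ivs:
        sf, fam, cls = subfams[rng.integers(len(subfams))]
        out.append(TECopy(iv, sf, fam, cls))
    return out


def targets_from_copies(copies):
    return [DNMT3CTarget(te, ("dmr_0",)) for te in copies]


# brute-force reference predicates kept deliberately naive


def brute_overlaps(a, b):
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def brute_overlaps_maxgap(a, b, maxgap):
    if a.chrom != b.chrom:
        return False
    return max(0, max(a.start, b.start) - min(a.end, b.end)) <= maxgap


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition synthetic genome shared across the session."""
    from tectool.simulate import SimulationConfig, simulate_genome

    return simulate_genome(SimulationConfig(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
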
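"""Readers and writers for the plain-text formats the pipeline exchanges.

Everything is text: BED (3/6 columns plus extras), FASTA (via Biopython),
bedGraph coverage, TSV count matrices and sample sheets, and MEME minimal
motif files. BED coordinates are kept 0-based half-open.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import DMR, DNMT3CTarget, GenomicInterval, TECopy


class FormatError(ValueError):
    """Raised for malformed records, naming the offending line."""


# ---------------------------------------------------------------- BED


def _parse_bed_line(line: str, path: str, lineno: int) -> list[str]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise FormatError(f"{path}:{lineno}: expected >=3 BED columns, got {len(fields)}")
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
    if not (0 <= start < end):
        raise FormatError(f"{path}:{lineno}: invalid interval {fields[0]}:{start}-{end}")
    return fields


def read_bed_intervals(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6; strand taken from column 6 when present."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = _parse_bed_line(line, str(path), lineno)
            strand = f[5] if len(f) >= 6 and f[5] in {"+", "-", "."} else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return out


def write_bed_intervals(path: str | Path, intervals: Iterable[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def read_dmrs(path: str | Path) -> list[DMR]:
    dmrs = []
    for i, iv in enumerate(read_bed_intervals(path)):
        dmrs.append(DMR(iv, name=f"dmr_{i}"))
    return dmrs


def read_te_bed(path: str | Path) -> list[TECopy]:
    """BED6+3: name=subfamily, columns 7/8 = family, class."""
    out: list[TECopy] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = _parse_bed_line(line, str(path), lineno)
            if len(f) < 8:
                raise FormatError(
                    f"{path}:{lineno}: TE BED needs 8 columns "
                    "(chrom start end subfamily score strand family class)"
                )
            iv = GenomicInterval(f[0], int(f[1]), int(f[2]), f[5] if f[5] in "+-." else ".")
            out.append(TECopy(iv, subfamily=f[3], family=f[6], te_class=f[7]))
    return out


def write_te_bed(path: str | Path, tes: Iterable[TECopy]) -> None:
    with open(path, "w") as fh:
        for te in tes:
            iv = te.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{te.subfamily}\t0\t{iv.strand}"
                f"\t{te.family}\t{te.te_class}\n"
            )


def write_targets_bed(path: str | Path, targets: Iterable[DNMT3CTarget]) -> None:
    """BED6+4: subfamily, family, class, number of supporting DMRs."""
    with open(path, "w") as fh:
        for t in targets:
            iv = t.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{t.te.subfamily}\t0\t{iv.strand}"
                f"\t{t.te.family}\t{t.te.te_class}\t{len(t.supporting_dmrs)}\n"
            )


def read_targets_bed(path: str | Path) -> list[DNMT3CTarget]:
    out: list[DNMT3CTarget] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = _parse_bed_line(line, str(path), lineno)
            if len(f) < 9:
                raise FormatError(f"{path}:{lineno}: target BED needs 9 columns")
            iv = GenomicInterval(f[0], int(f[1]), int(f[2]), f[5] if f[5] in "+-." else ".")
            te = TECopy(iv, subfamily=f[3], family=f[6], te_class=f[7])
            n = int(f[8])
            out.append(DNMT3CTarget(te, tuple(f"dmr_{i}" for i in range(n))))
    return out


# ---------------------------------------------------------------- FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------- bedGraph


def read_bedgraph(path: str | Path, chrom_sizes: dict[str, int]) -> dict[str, np.ndarray]:
    """Expand a bedGraph into per-base depth arrays (genome assumed small)."""
    tracks = {c: np.zeros(n, dtype=float) for c, n in chrom_sizes.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split()
            if len(f) < 4:
                raise FormatError(f"{path}:{lineno}: bedGraph needs 4 columns")
            chrom, start, end, value = f[0], int(f[1]), int(f[2]), float(f[3])
            if chrom not in tracks:
                continue
            tracks[chrom][start:end] = value
    return tracks


def write_bedgraph(path: str | Path, tracks: dict[str, np.ndarray]) -> None:
    """Run-length-encode per-base arrays into bedGraph lines (zeros skipped)."""
    with open(path, "w") as fh:
        for chrom in sorted(tracks):
            arr = np.asarray(tracks[chrom], dtype=float)
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0.0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


# ---------------------------------------------------------------- tables


def read_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise FormatError(f"{path}: negative counts")
    return df


def write_counts(path: str | Path, counts: pd.DataFrame) -> None:
    counts.to_csv(path, sep="\t")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "stage", "genotype", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: sample sheet missing columns {sorted(missing)}")
    return df


def write_sample_sheet(path: str | Path, sheet: pd.DataFrame) -> None:
    sheet.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- MEME motifs


def write_meme(path: str | Path, pwms: Sequence["PWM"]) -> None:  # noqa: F821
    from .bait import PWM  # local import to avoid a cycle

    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = pwms[0].background if pwms else np.full(4, 0.25)
        fh.write(
            "Background letter frequencies\n"
            f"A {bg[0]:.5f} C {bg[1]:.5f} G {bg[2]:.5f} T {bg[3]:.5f}\n\n"
        )
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= 20 E= 0\n"
            )
            for row in pwm.matrix:
                fh.write(" ".join(f"{p:.6f}" for p in row) + "\n")
            fh.write("\n")


def read_meme(path: str | Path) -> list["PWM"]:  # noqa: F821
    from .bait import PWM

    pwms: list[PWM] = []
    background = np.full(4, 0.25)
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            f = lines[i + 1].split()
            background = np.array([float(f[j]) for j in (1, 3, 5, 7)])
            i += 2
            continue
        if line.startswith("MOTIF"):
            name = line.split()[1]
            j = i + 1
            while j < len(lines) and "letter-probability matrix" not in lines[j]:
                j += 1
            if j == len(lines):
                raise FormatError(f"{path}: MOTIF {name} has no probability matrix")
            width = int(lines[j].split("w=")[1].split()[0])
            rows = []
            for k in range(j + 1, j + 1 + width):
                rows.append([float(x) for x in lines[k].split()])
            pwms.append(PWM(name=name, matrix=np.array(rows), background=background.copy()))
            i = j + 1 + width
            continue
        i += 1
    return pwms
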
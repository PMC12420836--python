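"""End-to-end orchestration: simulate -> targets -> classify -> profile ->
express -> diffte -> bait, with a manifest for reproducibility.

Every stage reads and writes plain-text TSV/BED/FASTA under the run
directory; the manifest records the seed, a config hash, per-stage row
counts and the SHA-256 of every output, so identical configs reproduce
byte-identical runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .bait import (
    enrichment_frame,
    methylate_in_silico,
    motif_enrichment,
    pulldown_enrichment,
    scramble_preserving_cpg,
    BaitSequence,
)
from .chromatin import (
    PeakSet,
    assignment_to_frame,
    category_composition,
    classify_targets,
    ChromatinCategory,
)
from .coverage import assign_multimappers, coverage_from_locations, profile_matrix, rpgc_normalize
from .diffenrich import NBTestConfig, aggregate_subfamilies, ma_table, nb_test, tmm_factors
from .expression import log_tpm, stage_zscores, stratified_expression_test, stratified_results_frame, tpm
from .simulate import (
    SimulationConfig,
    emit_all,
    extract_te_sequences,
    lengths_series,
    simulate_coverage_fragments,
    simulate_genome,
)
from .targets import build_high_confidence_te_set, define_dnmt3c_targets

log = logging.getLogger(__name__)

ALL_STAGES = ["simulate", "targets", "classify", "profile", "express", "diffte", "bait"]


@dataclass
class RunConfig:
    outdir: str = "tectool_run"
    seed: int = 0
    min_line_len: int = 5000
    min_ltr_len: int = 500
    maxgap_classify: int = 0
    maxgap_tf: int = 750
    alpha: float = 0.01
    log_base: float = 10.0
    zero_sentinel: float = -10.0
    lfc_threshold: float = 1.0
    p_threshold: float = 0.05
    flank: int = 3000
    binsize: int = 50
    high_confidence_for_classification: bool = False
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    simulation: SimulationConfig | None = None

    def sim_config(self) -> SimulationConfig:
        if self.simulation is not None:
            return self.simulation
        return SimulationConfig(seed=self.seed)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(type(o))

    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order; return the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(
        json.dumps(dataclasses.asdict(config), indent=1, sort_keys=True, default=str)
    )
    manifest: dict = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "stages": {},
    }
    sim_cfg = config.sim_config()
    state: dict = {}

    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        try:
            counts_info = _STAGE_FUNCS[stage](config, sim_cfg, outdir, state)
        except Exception:
            log.exception("stage %s failed; partial outputs kept in %s", stage, outdir)
            manifest["stages"][stage] = {"status": "failed"}
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
            raise
        files = {
            str(p.relative_to(outdir)): _sha256(p)
            for p in sorted(outdir.glob("**/*"))
            if p.is_file() and p.name not in ("manifest.json", "config.json")
        }
        manifest["stages"][stage] = {"status": "ok", **counts_info}
        manifest["files"] = files
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _stage_simulate(config: RunConfig, sim_cfg, outdir: Path, state: dict) -> dict:
    state["sim"] = simulate_genome(sim_cfg)
    state["paths"] = emit_all(sim_cfg, outdir / "inputs", sim=state["sim"])
    return {"n_te_copies": len(state["sim"].te_copies), "n_dmrs": len(state["sim"].dmrs)}


def _stage_targets(config: RunConfig, sim_cfg, outdir: Path, state: dict) -> dict:
    tes = tio.read_te_bed(state["paths"]["te"])
    dmrs = tio.read_dmrs(state["paths"]["dmr"])
    genes = tio.read_bed_intervals(state["paths"]["genes"])
    if config.high_confidence_for_classification:
        tes = build_high_confidence_te_set(tes, genes)
    targets = define_dnmt3c_targets(dmrs, tes, config.min_line_len, config.min_ltr_len)
    state["targets"] = targets
    state["genes"] = genes
    out = outdir / "targets.bed"
    tio.write_targets_bed(out, targets)
    return {"n_targets": len(targets)}


def _stage_classify(config: RunConfig, sim_cfg, outdir: Path, state: dict) -> dict:
    k4 = PeakSet("H3K4me3", tio.read_bed_intervals(state["paths"]["peaks_H3K4me3"]),
                 {"genotype": "KO", "stage": "Spg"})
    k27 = PeakSet("H3K27me3", tio.read_bed_intervals(state["paths"]["peaks_H3K27me3"]),
                  {"genotype": "KO", "stage": "Spg"})
    assignment = classify_targets(state["targets"], k4, k27, maxgap=config.maxgap_classify)
    state["assignment"] = assignment
    assignment_to_frame(assignment).to_csv(outdir / "assignment.tsv", sep="\t", index=False)
    comp = category_composition(assignment, state["targets"], by="family")
    comp.to_csv(outdir / "composition.tsv", sep="\t", index=False)
    counts = pd.Series([a.value for a in assignment.values()]).value_counts().to_dict()
    return {"n_classified": len(assignment), "category_counts": counts}


def _stage_profile(config: RunConfig, sim_cfg, outdir: Path, state: dict) -> dict:
    sim = state["sim"]
    fragments = simulate_coverage_fragments(sim, "H3K4me3", seed=config.seed + 10)
    placed = assign_multimappers(fragments, seed=config.seed + 11)
    track = rpgc_normalize(coverage_from_locations(placed, sim.chrom_sizes))
    tio.write_bedgraph(outdir / "H3K4me3_RPGC.bedgraph", track.depths)
    pm = profile_matrix(track, state["targets"], flank=config.flank,
                        binsize=config.binsize).ordered_by_mean()
    mat = pd.DataFrame(pm.matrix, index=pm.target_ids)
    mat.index.name = "target_id"
    mat.to_csv(outdir / "profile_matrix.tsv", sep="\t")
    pd.DataFrame({"bin": range(len(pm.metaplot)), "mean_coverage": pm.metaplot}).to_csv(
        outdir / "metaplot.tsv", sep="\t", index=False
    )
    (outdir / "profile_meta.json").write_text(json.dumps(
        {"row_order": "descending row mean", "flank": config.flank,
         "binsize": config.binsize, "n_skipped": pm.n_skipped}))
    return {"n_profiled": len(pm.target_ids)}


def _stage_express(config: RunConfig, sim_cfg, outdir: Path, state: dict) -> dict:
    counts = tio.read_counts(state["paths"]["counts"])
    samples = tio.read_sample_sheet(state["paths"]["samples"])
    lengths = pd.read_csv(state["paths"]["lengths"], sep="\t", index_col=0)["length"]
    tpm_mat = tpm(counts, lengths)
    tpm_mat.to_csv(outdir / "tpm.tsv", sep="\t")
    z = stage_zscores(tpm_mat, samples, grouping="family",
                      zero_sentinel=config.zero_sentinel)
    z.to_csv(outdir / "stage_zscores.tsv", sep="\t", index=False)
    logged = log_tpm(tpm_mat, zero_sentinel=config.zero_sentinel, base=config.log_base)
    results = stratified_expression_test(logged, state["assignment"], samples,
                                         zero_sentinel=config.zero_sentinel)
    state["stratified"] = results
    stratified_results_frame(results).to_csv(outdir / "stratified_tests.tsv",
                                             sep="\t", index=False)
    state["tpm"] = tpm_mat
    state["samples"] = samples
    state["counts"] = counts
    return {"n_loci": len(tpm_mat), "n_tests": len(results)}


def _stage_diffte(config: RunConfig, sim_cfg, outdir: Path, state: dict) -> dict:
    counts = state["counts"]
    samples = state["samples"]
    sim = state["sim"]
    meta = pd.DataFrame(
        {
            "subfamily": [te.subfamily for te in sim.te_copies],
            "family": [te.family for te in sim.te_copies],
            "te_class": [te.te_class for te in sim.te_copies],
        },
        index=pd.Index([te.locus_id for te in sim.te_copies], name="locus"),
    )
    subfam = aggregate_subfamilies(counts, meta)
    spg = samples[samples["stage"] == "Spg"]
    group_ko = spg[spg["genotype"] == "KO"]["sample"].tolist()
    group_wt = spg[spg["genotype"] == "WT"]["sample"].tolist()
    factors = tmm_factors(subfam[group_ko + group_wt])
    result = nb_test(subfam, factors, group_ko, group_wt,
                     NBTestConfig(alpha=config.alpha))
    result.to_csv(outdir / "diffte_KO_vs_WT_Spg.tsv", sep="\t")
    ma_table(result).to_csv(outdir / "ma_table_KO_vs_WT_Spg.tsv", sep="\t")
    state["diffte"] = result
    return {"n_subfamilies": len(result),
            "n_up": int((result["call"] == "Up").sum()),
            "n_down": int((result["call"] == "Down").sum())}


def _stage_bait(config: RunConfig, sim_cfg, outdir: Path, state: dict) -> dict:
    sim = state["sim"]
    # baits: promoter of one IAPLTR1a copy carrying the planted motif, plus
    # its CpG-preserving scrambled control
    ltr_copies = [te for te in sim.te_copies
                  if te.subfamily == "IAPLTR1a" and te.locus_id in sim.motif_copies]
    if not ltr_copies:
        ltr_copies = [te for te in sim.te_copies if te.subfamily == "IAPLTR1a"]
    promoter = extract_te_sequences(sim, ltr_copies[:1], promoter_only=True)
    bait_seq = next(iter(promoter.values()))
    scrambled = scramble_preserving_cpg(bait_seq, seed=config.seed + 20)
    bait = BaitSequence("IAPLTR1a_bait", bait_seq)
    meth = methylate_in_silico(bait)
    tio.write_fasta(outdir / "baits.fa", {
        "IAPLTR1a_bait": bait.sequence,
        "IAPLTR1a_scrambled": scrambled,
    })
    with open(outdir / "baits_provenance.txt", "w") as fh:
        fh.write(f"seed\t{config.seed + 20}\n")
        fh.write(f"cpg_positions_preserved\t{bait.cpg_positions == BaitSequence('s', scrambled).cpg_positions}\n")
        fh.write(f"n_cpg\t{len(meth.methylation_records)}\n")

    tables = {
        cond: pd.read_csv(state["paths"][f"pulldown_{cond}"], sep="\t", index_col=0)
        for cond in ("bait_unmethylated", "bait_methylated",
                     "scrambled_unmethylated", "scrambled_methylated")
    }
    calls = pulldown_enrichment(tables, config.lfc_threshold, config.p_threshold)
    frame = enrichment_frame(calls)
    with open(outdir / "pulldown_enrichment.tsv", "w") as fh:
        fh.write(f"# lfc_threshold={config.lfc_threshold} p_threshold={config.p_threshold}\n")
        frame.to_csv(fh, sep="\t")
    state["pulldown"] = frame

    genes = state.get("genes", [])
    hc = build_high_confidence_te_set(sim.te_copies, genes)
    hc_ids = {te.locus_id for te in hc}
    target_ids = {t.te.locus_id for t in state["targets"]}
    target_seqs = extract_te_sequences(
        sim, [te for te in hc if te.locus_id in target_ids], promoter_only=True
    )
    background_seqs = extract_te_sequences(sim, hc, promoter_only=True)
    pwms = tio.read_meme(state["paths"]["motifs"])
    enr = motif_enrichment(target_seqs, background_seqs, pwms)
    enr.to_csv(outdir / "motif_enrichment.tsv", sep="\t")
    state["motif_enrichment"] = enr
    return {
        "n_sequence_specific": int(frame["sequence_specific"].sum()),
        "n_motifs_tested": len(enr),
        "n_hc_tes": len(hc_ids),
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "targets": _stage_targets,
    "classify": _stage_classify,
    "profile": _stage_profile,
    "express": _stage_express,
    "diffte": _stage_diffte,
    "bait": _stage_bait,
}
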
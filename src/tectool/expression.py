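"""Locus-level TE expression: TPM, log conventions, stage z-scores, and
category-stratified comparisons.

TPM per column: ``rate_i = count_i / length_i``; ``TPM_i = 1e6 * rate_i /
sum(rates)``. Zero TPM values map to a sentinel (default -10 on a log10
axis) so silent loci remain visible in plotted distributions.

Stage z-scores summarize expression dynamics per TE family (or subfamily):
the per-stage mean of log TPM is standardized against the mean and
population SD of those stage means, so each row has mean 0 / SD 1 across
stages (degenerate constant rows score 0 everywhere).

Stratified comparisons test whether likely-bivalent targets differ in
expression from each other chromatin category within a stage x genotype,
using Welch's unpaired t test by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .chromatin import CATEGORY_ORDER, ChromatinCategory

ZERO_SENTINEL = -10.0


def tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million per column; all-zero columns stay all-zero."""
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths[lengths.isna()].index.tolist()
        raise ValueError(f"missing lengths for rows: {missing[:5]}")
    if (lengths <= 0).any():
        raise ValueError("all effective lengths must be > 0")
    rates = counts.div(lengths, axis=0)
    totals = rates.sum(axis=0)
    out = rates.div(totals.where(totals > 0, np.nan), axis=1) * 1e6
    return out.fillna(0.0)


def log_tpm(
    tpm_values: pd.DataFrame | pd.Series | np.ndarray,
    zero_sentinel: float = ZERO_SENTINEL,
    base: float = 10.0,
) -> pd.DataFrame | pd.Series | np.ndarray:
    """log(TPM) with zeros mapped to the sentinel (monotone on positives)."""
    arr = np.asarray(tpm_values, dtype=float)
    with np.errstate(divide="ignore"):
        logged = np.log(arr) / np.log(base)
    logged = np.where(arr > 0, logged, zero_sentinel)
    if isinstance(tpm_values, pd.DataFrame):
        return pd.DataFrame(logged, index=tpm_values.index, columns=tpm_values.columns)
    if isinstance(tpm_values, pd.Series):
        return pd.Series(logged, index=tpm_values.index)
    return logged


def _locus_group(index: pd.Index, grouping: str) -> pd.Series:
    """Extract family or subfamily from 'subfamily|chrom:start-end|strand' ids.

    When ids carry a 'subfamily:family:class' prefix, family is the middle
    token; otherwise the subfamily token itself is used for both groupings.
    """
    subfam = index.to_series().str.split("|").str[0]
    if grouping == "subfamily":
        return subfam.str.split(":").str[0]
    if grouping == "family":
        parts = subfam.str.split(":")
        return parts.map(lambda p: p[1] if len(p) >= 2 else p[0])
    raise ValueError(f"unknown grouping {grouping!r}")


def stage_zscores(
    tpm_values: pd.DataFrame,
    samples: pd.DataFrame,
    grouping: str = "family",
    zero_sentinel: float = ZERO_SENTINEL,
    sd_over: str = "stage_means",
) -> pd.DataFrame:
    """Per group x stage z-scores of mean log TPM.

    ``sd_over='stage_means'`` (default) standardizes against the population
    SD of the per-stage means; ``'samples'`` uses the SD over all per-sample
    group means instead.
    """
    stages = samples.set_index("sample")["stage"].reindex(tpm_values.columns)
    if stages.isna().any():
        raise ValueError("sample sheet does not cover all count columns")
    if stages.nunique() < 2:
        raise ValueError("stage z-scores need >= 2 stages")
    logged = log_tpm(tpm_values, zero_sentinel=zero_sentinel)
    groups = _locus_group(tpm_values.index, grouping)
    # mean over member loci then over the stage's samples
    per_sample = logged.groupby(groups).mean()
    stage_means = per_sample.T.groupby(stages).mean().T  # group x stage

    mu = stage_means.mean(axis=1)
    if sd_over == "stage_means":
        sd = stage_means.std(axis=1, ddof=0)
    elif sd_over == "samples":
        sd = per_sample.std(axis=1, ddof=0)
    else:
        raise ValueError(f"unknown sd_over {sd_over!r}")
    z = stage_means.sub(mu, axis=0).div(sd.where(sd > 0, np.nan), axis=0).fillna(0.0)
    out = z.stack().rename("z").reset_index()
    out.columns = ["group", "stage", "z"]
    means_long = stage_means.stack().rename("mean_log_tpm").reset_index()
    means_long.columns = ["group", "stage", "mean_log_tpm"]
    return out.merge(means_long, on=["group", "stage"])


@dataclass
class StratifiedTestResult:
    stage: str
    genotype: str
    other_category: str
    t_statistic: float
    p_value: float
    n_bivalent: int
    n_other: int
    skipped_reason: str = ""


def stratified_expression_test(
    log_tpm_values: pd.DataFrame,
    assignment: Mapping[str, ChromatinCategory],
    samples: pd.DataFrame,
    equal_var: bool = False,
    include_sentinel: bool = True,
    zero_sentinel: float = ZERO_SENTINEL,
) -> list[StratifiedTestResult]:
    """Welch t tests of likely-bivalent vs each other category per stage x genotype.

    Each locus contributes its mean log TPM over that condition's samples.
    Groups with fewer than 2 loci are skipped with a reason.
    """
    meta = samples.set_index("sample")
    results: list[StratifiedTestResult] = []
    cats = pd.Series({k: v.value for k, v in assignment.items()})
    common = log_tpm_values.index.intersection(cats.index)
    cats = cats.loc[common]
    for (stage, genotype), cond in meta.groupby(["stage", "genotype"], sort=True):
        cols = [c for c in cond.index if c in log_tpm_values.columns]
        if not cols:
            continue
        locus_means = log_tpm_values.loc[common, cols].mean(axis=1)
        if not include_sentinel:
            locus_means = locus_means[locus_means > zero_sentinel]
        biv = locus_means[cats.reindex(locus_means.index) == ChromatinCategory.LIKELY_BIVALENT.value]
        for cat in CATEGORY_ORDER:
            if cat is ChromatinCategory.LIKELY_BIVALENT:
                continue
            other = locus_means[cats.reindex(locus_means.index) == cat.value]
            if len(biv) < 2 or len(other) < 2:
                results.append(
                    StratifiedTestResult(
                        stage, genotype, cat.value, np.nan, np.nan,
                        len(biv), len(other), skipped_reason="group size < 2",
                    )
                )
                continue
            t, p = stats.ttest_ind(biv, other, equal_var=equal_var)
            results.append(
                StratifiedTestResult(stage, genotype, cat.value, float(t), float(p),
                                     len(biv), len(other))
            )
    return results


def stratified_results_frame(results: Sequence[StratifiedTestResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
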
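"""Subfamily-level differential TE enrichment.

Implements the TMM / negative-binomial contract used for both the RNA and
the CUT&Tag enrichment comparisons:

* locus counts aggregated to subfamilies (column sums conserved),
* between-sample normalization by the trimmed mean of M-values (TMM):
  per-sample log2 ratios (M) against a reference column are trimmed (30% on
  M, 5% on absolute intensity A), inverse-variance weighted, and the
  resulting factors rescaled to geometric mean 1,
* an exact conditional negative-binomial test per subfamily on
  library-size-equalized pseudo-counts, with a method-of-moments common
  dispersion (variance mu + alpha*mu^2) and the two-sided p obtained by
  doubling the smaller conditional tail,
* Benjamini-Hochberg adjustment across tested rows, calls Up/Down/NotSig at
  adjusted p < alpha (default 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

DEFAULT_ALPHA = 0.01
FC_PRIOR = 0.5  # per-library prior count for fold changes
LOGCPM_PRIOR = 2.0  # prior count for average logCPM


def aggregate_subfamilies(
    counts: pd.DataFrame, te_metadata: pd.DataFrame
) -> pd.DataFrame:
    """Sum locus rows into subfamily rows labelled ``name:family:class``.

    ``te_metadata`` is indexed by locus id with columns subfamily, family,
    te_class. Every locus row must be mapped.
    """
    unmapped = counts.index.difference(te_metadata.index)
    if len(unmapped) > 0:
        raise ValueError(f"loci missing from metadata: {list(unmapped[:5])}")
    meta = te_metadata.loc[counts.index]
    labels = meta["subfamily"] + ":" + meta["family"] + ":" + meta["te_class"]
    out = counts.groupby(labels.values).sum()
    out.index.name = "subfamily"
    return out.sort_index()


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def tmm_factors(
    counts: pd.DataFrame,
    trim_logfc: float = 0.30,
    trim_abs: float = 0.05,
    ref_column: str | None = None,
) -> pd.Series:
    """Per-sample TMM normalization factors, geometric mean exactly 1."""
    x = counts.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("TMM needs >= 2 samples")
    lib = x.sum(axis=0)
    if (lib == 0).any():
        bad = counts.columns[lib == 0].tolist()
        raise ValueError(f"all-zero columns: {bad}")
    props = x / lib
    if ref_column is None:
        uq = np.array([np.quantile(props[:, k], 0.75) for k in range(x.shape[1])])
        ref = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref = counts.columns.get_loc(ref_column)

    factors = np.ones(x.shape[1])
    for k in range(x.shape[1]):
        if k == ref:
            factors[k] = 1.0
            continue
        factors[k] = 2.0 ** _tmm_one(x[:, k], x[:, ref], lib[k], lib[ref],
                                     trim_logfc, trim_abs)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def _tmm_one(obs, ref, n_obs, n_ref, trim_logfc, trim_abs) -> float:
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep], ref[keep]
    if obs.size == 0:
        return 0.0
    m = np.log2((obs / n_obs) / (ref / n_ref))
    a = 0.5 * np.log2((obs / n_obs) * (ref / n_ref))
    # delta-method variance of M
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    if np.max(np.abs(m)) < 1e-6:  # identical composition
        return 0.0
    n = m.size
    lo_m = np.floor(n * trim_logfc) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_abs) + 1
    hi_a = n + 1 - lo_a
    rm = stats.rankdata(m)
    ra = stats.rankdata(a)
    keep2 = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep2.any():
        return 0.0
    w = 1.0 / v[keep2]
    return float(np.sum(w * m[keep2]) / np.sum(w))


@dataclass
class NBTestConfig:
    alpha: float = DEFAULT_ALPHA
    dispersion: float | None = None  # None -> method-of-moments estimate
    min_dispersion: float = 1e-8


def estimate_common_dispersion(pseudo: np.ndarray, groups: np.ndarray) -> float:
    """Method-of-moments common dispersion on equalized pseudo-counts.

    Per-row alpha_g = (pooled within-group variance - mean) / mean^2,
    averaged over informative rows and clipped at >= 0.
    """
    ests = []
    for g in np.unique(groups):
        sub = pseudo[:, groups == g]
        if sub.shape[1] < 2:
            raise ValueError("dispersion estimation needs >= 2 replicates per group")
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (v[ok] - m[ok]) / m[ok] ** 2
        ests.append(a)
    all_est = np.concatenate(ests)
    if all_est.size == 0:
        return 0.0
    return float(max(np.mean(all_est), 0.0))


def _nb_logpmf_grid(x: np.ndarray, mean: float, size: float) -> np.ndarray:
    p = size / (size + mean)
    return (
        gammaln(x + size) - gammaln(size) - gammaln(x + 1)
        + size * np.log(p) + x * np.log1p(-p)
    )


def exact_nb_pvalue(s1: float, s2: float, n1: int, n2: int, dispersion: float) -> float:
    """Two-sided exact conditional NB test for group sums of pseudo-counts.

    Sums of replicates are NB with size n/alpha; conditioning on the total,
    the p-value doubles the smaller tail of P(S1 | S1 + S2).
    """
    s1r, s2r = int(round(s1)), int(round(s2))
    s = s1r + s2r  # consistent rounding keeps the test exactly symmetric
    if s == 0:
        return 1.0
    mu = s / (n1 + n2)
    disp = max(dispersion, 1e-10)
    size1, size2 = n1 / disp, n2 / disp
    m1, m2 = n1 * mu, n2 * mu
    # enumerate a window around the conditional mode with negligible tail loss
    frac = n1 / (n1 + n2)
    center = s * frac
    sd = np.sqrt(max(m1 + disp * m1 * m1 / n1, 1.0))
    half = int(max(40 * sd, 50))
    lo = max(0, int(center) - half)
    hi = min(s, int(center) + half)
    if hi - lo > 100_000:
        # counts this large are safely Gaussian; doubling the smaller
        # normal tail mirrors the exact computation
        v1 = m1 + disp * m1 * m1 / n1
        v2 = m2 + disp * m2 * m2 / n2
        cond_var = v1 * v2 / (v1 + v2)
        z = (s1r - center) / np.sqrt(cond_var)
        from scipy.stats import norm

        return float(min(2.0 * norm.sf(abs(z)), 1.0))
    xs = np.arange(lo, hi + 1, dtype=float)
    logp = _nb_logpmf_grid(xs, m1, size1) + _nb_logpmf_grid(s - xs, m2, size2)
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    s1c = min(max(s1r, lo), hi)  # clamping keeps tails correct: mass outside is negligible
    bottom = probs[xs <= s1c].sum()
    top = probs[xs >= s1c].sum()
    return float(min(2.0 * min(bottom, top), 1.0))


def nb_test(
    counts: pd.DataFrame,
    factors: pd.Series | None,
    group_a: list[str],
    group_b: list[str],
    config: NBTestConfig | None = None,
) -> pd.DataFrame:
    """Differential test of ``group_a`` vs ``group_b`` (log2FC = A over B).

    Returns a frame with log2FC, logCPM, pvalue, padj and call per subfamily.
    """
    config = config or NBTestConfig()
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 replicates per group (dispersion unidentifiable)")
    cols = list(group_a) + list(group_b)
    x = counts[cols].to_numpy(dtype=float)
    lib = x.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("all-zero sample column")
    f = (
        factors.reindex(cols).to_numpy(dtype=float)
        if factors is not None
        else np.ones(len(cols))
    )
    eff_lib = lib * f
    geo = np.exp(np.mean(np.log(eff_lib)))
    pseudo = x * (geo / eff_lib)  # library-size-equalized
    groups = np.array([0] * len(group_a) + [1] * len(group_b))

    disp = (
        config.dispersion
        if config.dispersion is not None
        else estimate_common_dispersion(pseudo, groups)
    )
    if config.dispersion is not None and config.dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    disp = max(disp, config.min_dispersion)

    n1, n2 = len(group_a), len(group_b)
    s1 = pseudo[:, groups == 0].sum(axis=1)
    s2 = pseudo[:, groups == 1].sum(axis=1)
    pvals = np.array([exact_nb_pvalue(a, b, n1, n2, disp) for a, b in zip(s1, s2)])
    padj = benjamini_hochberg(pvals)

    mean_a = pseudo[:, groups == 0].mean(axis=1)
    mean_b = pseudo[:, groups == 1].mean(axis=1)
    prior = FC_PRIOR * geo / 1e6  # 0.5 counts per million of library depth
    log2fc = np.log2(mean_a + prior) - np.log2(mean_b + prior)
    logcpm = np.log2(
        1e6 * (x.sum(axis=1) + 2 * LOGCPM_PRIOR) / (eff_lib.sum() + 2 * LOGCPM_PRIOR)
    )

    call = np.where(
        padj < config.alpha, np.where(log2fc > 0, "Up", "Down"), "NotSig"
    )
    # a significant row with exactly zero FC cannot be directional
    call = np.where((padj < config.alpha) & (log2fc == 0), "NotSig", call)
    return pd.DataFrame(
        {
            "log2FC": log2fc,
            "logCPM": logcpm,
            "pvalue": pvals,
            "padj": padj,
            "call": call,
            "dispersion": disp,
        },
        index=counts.index,
    )


def ma_table(result: pd.DataFrame) -> pd.DataFrame:
    """MA-plot table: one row per subfamily with logCPM, log2FC and call."""
    required = {"log2FC", "logCPM", "call"}
    missing = required - set(result.columns)
    if missing:
        raise ValueError(f"result missing columns {sorted(missing)}")
    return result[["logCPM", "log2FC", "call"]].copy()
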
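"""Cis-regulatory lncRNA scan and negative-binomial disease-cohort DE.

A lncRNA whose expression tracks an adjacent protein-coding gene across a
cohort of islet samples is a candidate cis-regulator.  The scan pairs each
lncRNA with its nearest coding gene (gene-body interval distance, BED
0-based half-open, 1 Mb window by default) and calls the pair a candidate
when the Pearson correlation p-value clears a stringent threshold
(default 1e-7).

For case/control count data (islets from impaired-glucose-tolerance or
type 2 diabetes donors vs normoglycemic controls) a simplified
negative-binomial Wald test is provided: median-of-ratios size factors,
method-of-moments dispersion, Wald statistic on the log2 fold change, and
Benjamini-Hochberg adjustment.  This is deliberately a lean NB core — no
dispersion shrinkage or outlier refitting — aimed at the thresholding
logic (padj < 0.05) and effect directions rather than at reproducing any
particular DE tool's internals.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "nearest_coding_gene",
    "correlation_pvalue",
    "cis_pair_scan",
    "size_factors",
    "nb_wald_de",
    "bh_adjust",
]

CODING_BIOTYPES = {"coding", "TF"}


def _interval_distance(s1: int, e1: int, s2: int, e2: int) -> int:
    """Gap between two 0-based half-open intervals; 0 when they overlap."""
    return max(0, max(s1, s2) - min(e1, e2))


def nearest_coding_gene(
    lnc_id: str,
    annot: pd.DataFrame,
    max_distance: int = 1_000_000,
    mode: str = "gene_body",
) -> pd.Series | None:
    """Nearest protein-coding (or TF) gene to a lncRNA on its chromosome.

    Distance is the gene-body interval gap (0 if overlapping); ``mode="tss"``
    uses the absolute distance between transcription start sites instead.
    Exact ties are broken toward the gene on the lncRNA's 5' side, then by
    lexicographic id.  Returns the annotation row of the partner, or None
    if no coding gene lies within ``max_distance``.
    """
    rows = annot[annot["gene_id"] == lnc_id]
    if rows.empty:
        raise KeyError(f"lncRNA {lnc_id!r} absent from annotation")
    lnc = rows.iloc[0]
    coding = annot[(annot["biotype"].isin(CODING_BIOTYPES)) & (annot["chrom"] == lnc["chrom"])]
    if coding.empty:
        return None

    starts = coding["start"].to_numpy(dtype=np.int64)
    ends = coding["end"].to_numpy(dtype=np.int64)
    if mode == "tss":
        lnc_tss = int(lnc["start"]) if lnc["strand"] == "+" else int(lnc["end"])
        cand_tss = np.where(coding["strand"].to_numpy() == "+", starts, ends)
        dist = np.abs(cand_tss - lnc_tss)
    else:
        dist = np.maximum(0, np.maximum(int(lnc["start"]), starts)
                          - np.minimum(int(lnc["end"]), ends))
    # 5'-side of the lncRNA: lower coordinates for '+' strand, higher for '-'
    if lnc["strand"] == "-":
        five_prime = starts >= int(lnc["end"])
    else:
        five_prime = ends <= int(lnc["start"])
    within = dist <= max_distance
    if not within.any():
        return None
    keys = sorted(
        zip(dist[within], np.where(five_prime[within], 0, 1),
            coding.loc[within, "gene_id"], np.flatnonzero(within)),
    )
    d_best, _, _, pos = keys[0]
    partner = coding.iloc[pos].copy()
    partner["distance"] = int(d_best)
    return partner


def correlation_pvalue(x, y) -> tuple[float, float]:
    """Pearson r with the two-sided t-distribution p-value (df = n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched samples of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        return float(np.sign(r)), 0.0
    df = x.size - 2
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(p)


def cis_pair_scan(
    expr: pd.DataFrame,
    annot: pd.DataFrame,
    p_threshold: float = 1e-7,
    max_distance: int = 1_000_000,
    mode: str = "gene_body",
) -> pd.DataFrame:
    """Correlation of every lncRNA with its nearest coding gene.

    Returns a table (lncRNA, partner, distance, r, p, candidate) with
    candidate == (p < p_threshold).  lncRNAs lacking a coding gene within
    the window, or lacking expression data, are excluded with a log line.
    """
    if not annot["biotype"].isin(CODING_BIOTYPES).any():
        raise ValueError("annotation contains no coding genes")
    rows = []
    lncs = annot[annot["biotype"] == "lncRNA"]
    for _, lnc in lncs.iterrows():
        lnc_id = lnc["gene_id"]
        if lnc_id not in expr.index:
            logger.info("lncRNA %s has no expression row; excluded", lnc_id)
            continue
        partner = nearest_coding_gene(lnc_id, annot, max_distance, mode)
        if partner is None:
            logger.info("lncRNA %s has no coding gene within %d bp; excluded",
                        lnc_id, max_distance)
            continue
        pid = partner["gene_id"]
        if pid not in expr.index:
            logger.info("partner %s of %s has no expression row; excluded", pid, lnc_id)
            continue
        r, p = correlation_pvalue(expr.loc[lnc_id], expr.loc[pid])
        rows.append({"lncRNA": lnc_id, "partner": pid,
                     "distance": int(partner["distance"]), "r": r, "p": p,
                     "candidate": p < p_threshold})
    return pd.DataFrame(rows, columns=["lncRNA", "partner", "distance", "r", "p", "candidate"])


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    For each gene expressed in every sample, the ratio of its count to its
    geometric mean across samples; a sample's size factor is the median of
    those ratios.
    """
    K = counts.to_numpy(dtype=float)
    all_pos = (K > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError("no gene with nonzero counts in all samples")
    logK = np.log(K[all_pos])
    log_geo = logK.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logK - log_geo, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def nb_wald_de(
    counts: pd.DataFrame,
    conditions: pd.Series,
    sf: pd.Series | None = None,
    alpha: float = 0.05,
    dispersion_floor: float = 1e-8,
    reference: str | None = None,
) -> pd.DataFrame:
    """Two-condition negative-binomial Wald differential expression.

    Counts are normalized by size factors (median-of-ratios if not given);
    per-condition means come from the normalized counts; the NB dispersion
    is estimated by the method of moments pooled across conditions and
    floored at ``dispersion_floor``.  The Wald statistic tests the log2
    fold change of the non-reference condition over the reference (a level
    named "control" is the reference by default, else the lexicographically
    first level).  BH-adjusted p-values gate significance at ``alpha``.
    Genes with an all-zero condition get NA statistics.
    """
    conditions = conditions.loc[counts.columns]
    levels = sorted(conditions.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 conditions, got {levels}")
    if reference is None:
        reference = "control" if "control" in levels else levels[0]
    if reference not in levels:
        raise ValueError(f"reference {reference!r} not among conditions {levels}")
    levels = [reference] + [lev for lev in levels if lev != reference]
    for lev in levels:
        if (conditions == lev).sum() < 2:
            raise ValueError(f"condition {lev!r} has fewer than 2 samples")
    if sf is None:
        sf = size_factors(counts)
    sf = sf.loc[counts.columns].to_numpy(dtype=float)
    if (sf <= 0).any():
        raise ValueError("size factors must be positive")

    K = counts.to_numpy(dtype=float)
    Q = K / sf  # normalized counts
    masks = [(conditions == lev).to_numpy() for lev in levels]
    n = [int(m.sum()) for m in masks]
    mu = [Q[:, m].mean(axis=1) for m in masks]  # per-condition normalized means

    # method-of-moments dispersion on the normalized scale, pooled:
    # Var(q_j) ~ mu * (1/sf_j) + alpha_disp * mu^2
    inv_sf_mean = [np.mean(1.0 / sf[m]) for m in masks]
    num = np.zeros(K.shape[0])
    den = np.zeros(K.shape[0])
    for c in range(2):
        v = Q[:, masks[c]].var(axis=1, ddof=1)
        num += (n[c] - 1) * (v - mu[c] * inv_sf_mean[c])
        den += (n[c] - 1) * mu[c] ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(den > 0, num / den, np.nan)
    disp = np.maximum(disp, dispersion_floor)

    valid = (mu[0] > 0) & (mu[1] > 0)
    log2fc = np.full(K.shape[0], np.nan)
    wald = np.full(K.shape[0], np.nan)
    p = np.full(K.shape[0], np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc[valid] = np.log2(mu[1][valid] / mu[0][valid])
        # delta-method variance of log2(mean) per condition
        var_log2 = np.zeros(K.shape[0])
        for c in range(2):
            var_mean = (mu[c] * inv_sf_mean[c] + disp * mu[c] ** 2) / n[c]
            var_log2 += np.where(valid, var_mean / (mu[c] ** 2 * np.log(2) ** 2), np.nan)
        se = np.sqrt(var_log2)
        wald[valid] = log2fc[valid] / se[valid]
    p[valid] = 2.0 * stats.norm.sf(np.abs(wald[valid]))

    padj = np.full(K.shape[0], np.nan)
    if valid.any():
        padj[valid] = bh_adjust(p[valid])
    table = pd.DataFrame(
        {"baseMean": Q.mean(axis=1), "log2fc": log2fc, "dispersion": disp,
         "stat": wald, "p": p, "padj": padj},
        index=counts.index,
    )
    table["significant"] = table["padj"] < alpha
    return table


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
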
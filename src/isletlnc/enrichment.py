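"""Gene-set enrichment with expression-matched control sets.

A knockdown phenotype is tested against a curated gene set (for instance
genes associated with islet enhancer clusters) by weighted
Kolmogorov-Smirnov GSEA on the fold-change ranking.  Because highly
expressed genes are both easier to detect as differential and more likely
to sit in curated sets, enrichment is benchmarked against control sets
sampled to match the target set's expression-level profile bin by bin.
Hypergeometric upper-tail enrichment serves categorical annotation of
co-expression modules, and the tissue-panel rule defines islet-enriched
genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "islet_enriched_genes",
    "expression_matched_control_sets",
    "gsea_enrichment_score",
    "gsea_permutation_p",
    "hypergeometric_enrichment",
]


@dataclass
class GeneSetCollection:
    """Named gene sets over a common universe (GMT semantics)."""

    sets: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = set().union(*self.sets.values()) if self.sets else set()
        for name, members in self.sets.items():
            stray = members - self.universe
            if stray:
                raise ValueError(f"set {name!r} has members outside the universe: {sorted(stray)[:5]}")

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


def islet_enriched_genes(focal_expr: pd.Series, panel: pd.DataFrame) -> set[str]:
    """Genes whose focal-tissue expression exceeds the tissue-panel mean by
    more than two panel standard deviations (sample SD, strict inequality)."""
    if panel.shape[1] < 2:
        raise ValueError("panel needs at least 2 tissues")
    if not focal_expr.index.equals(panel.index):
        if set(focal_expr.index) != set(panel.index):
            raise ValueError("focal and panel gene universes differ")
        panel = panel.loc[focal_expr.index]
    mean = panel.mean(axis=1)
    sd = panel.std(axis=1, ddof=1)
    keep = focal_expr > mean + 2.0 * sd
    return set(focal_expr.index[keep])


def expression_matched_control_sets(
    target_set: set[str],
    mean_expr: pd.Series,
    n_sets: int = 10,
    n_bins: int = 10,
    seed: int | None = None,
) -> list[set[str]]:
    """Random gene sets matching the target set's expression-bin profile.

    Genes are split into ``n_bins`` quantile bins of mean expression; each
    control set draws, without replacement and excluding the target set,
    the same number of genes per bin as the target set occupies.  When a
    bin has too few non-target genes the deficit is borrowed from the
    nearest neighbouring bins (logged).
    """
    rng = np.random.default_rng(seed)
    missing = target_set - set(mean_expr.index)
    if missing:
        raise ValueError(f"target genes without expression values: {sorted(missing)[:5]}")
    bins = pd.qcut(mean_expr.rank(method="first"), n_bins, labels=False)
    target_profile = bins.loc[sorted(target_set)].value_counts().to_dict()
    nontarget_by_bin = {
        b: sorted(set(mean_expr.index[bins == b]) - target_set) for b in range(n_bins)
    }

    out: list[set[str]] = []
    for _ in range(n_sets):
        chosen: list[str] = []
        for b, quota in sorted(target_profile.items()):
            pool = nontarget_by_bin[b]
            take = min(quota, len(pool))
            chosen.extend(rng.choice(pool, size=take, replace=False))
            deficit = quota - take
            offset = 1
            while deficit > 0:
                neighbours = [b - offset, b + offset]
                for nb in neighbours:
                    if deficit == 0 or not (0 <= nb < n_bins):
                        continue
                    pool_nb = sorted(set(nontarget_by_bin[nb]) - set(chosen))
                    take_nb = min(deficit, len(pool_nb))
                    if take_nb:
                        logger.warning(
                            "bin %d short by %d genes; borrowing %d from bin %d",
                            b, deficit, take_nb, nb,
                        )
                        chosen.extend(rng.choice(pool_nb, size=take_nb, replace=False))
                        deficit -= take_nb
                offset += 1
                if offset > n_bins:
                    raise ValueError(f"cannot fill quota for bin {b}: universe too small")
        out.append(set(chosen))
    return out


def gsea_enrichment_score(
    ranked: pd.Series,
    gene_set: set[str],
    weight_exponent: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Weighted Kolmogorov-Smirnov enrichment score.

    ``ranked`` maps gene id to score and is sorted by score descending
    internally.  Walking down the ranking, hits increment the running sum
    by |score|^w normalized over hits, misses decrement by 1/(N - N_hits);
    ES is the running-sum value of largest magnitude (signed).  A set
    concentrated at the top gives ES near +1, at the bottom near -1.
    """
    ranked = ranked.sort_values(ascending=False, kind="mergesort")
    ids = ranked.index.to_numpy()
    scores = ranked.to_numpy(dtype=float)
    ishit = np.isin(ids, list(gene_set))
    n, nhit = ids.size, int(ishit.sum())
    if nhit == 0:
        raise ValueError("gene set does not intersect the ranking")
    weights = np.abs(scores) ** weight_exponent
    hit_norm = weights[ishit].sum()
    if hit_norm == 0:
        # all hit scores are exactly zero: fall back to equal hit weights
        steps = np.where(ishit, 1.0 / nhit, 0.0)
    else:
        steps = np.where(ishit, weights / hit_norm, 0.0)
    if n > nhit:
        steps = steps - np.where(ishit, 0.0, 1.0 / (n - nhit))
    running = np.cumsum(steps)
    es = float(running[np.argmax(np.abs(running))])
    return es, running


def gsea_permutation_p(
    ranked: pd.Series,
    gene_set: set[str],
    n_perm: int = 1000,
    seed: int | None = None,
    weight_exponent: float = 1.0,
) -> tuple[float, float]:
    """Gene-set permutation p-value and normalized enrichment score.

    The null draws random gene sets of equal size from the ranking.  The
    one-sided p counts permuted ES of the same sign with magnitude >= |ES|,
    with the +1 correction; NES divides ES by the mean |ES_perm| of the
    same sign.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    es, _ = gsea_enrichment_score(ranked, gene_set, weight_exponent)
    size = len(gene_set & set(ranked.index))
    universe = np.asarray(ranked.index)
    perm_es = np.empty(n_perm)
    for i in range(n_perm):
        perm = set(rng.choice(universe, size=size, replace=False))
        perm_es[i], _ = gsea_enrichment_score(ranked, perm, weight_exponent)
    same_sign = perm_es * es >= 0
    if np.all(perm_es == perm_es[0]):
        raise ValueError("degenerate permutation null: all permuted ES identical")
    p = (1 + int(np.sum(same_sign & (np.abs(perm_es) >= abs(es))))) / (1 + n_perm)
    denom = np.abs(perm_es[same_sign]).mean() if same_sign.any() else np.nan
    nes = es / denom if denom and denom > 0 else np.nan
    return float(p), float(nes)


def hypergeometric_enrichment(
    module_genes: set[str],
    annotation_set: set[str],
    universe: set[str],
) -> float:
    """Upper-tail hypergeometric p for the module/annotation overlap.

    P(X >= k) with X ~ Hypergeom(N=|universe|, K=|annotation|, n=|module|)
    and k the observed overlap.
    """
    if not universe:
        raise ValueError("empty universe")
    if not module_genes <= universe or not annotation_set <= universe:
        raise ValueError("module and annotation must be subsets of the universe")
    N, K, n = len(universe), len(annotation_set), len(module_genes)
    k = len(module_genes & annotation_set)
    if k > min(K, n):  # pragma: no cover - guarded by set algebra
        raise ValueError("impossible overlap")
    return float(stats.hypergeom.sf(k - 1, N, K, n))
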
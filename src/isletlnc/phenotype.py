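"""Shared transcriptional programs across knockdowns.

Different regulators that sit in one network should dysregulate overlapping
gene sets when silenced.  This module quantifies that: fold changes of the
genes significant in at least one knockdown are collected into a matrix,
contrasts are correlated pairwise (Pearson), clustered (average linkage on
1 - r) and compared on their most strongly regulated genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "FoldChangeMatrix",
    "build_foldchange_matrix",
    "pairwise_phenotype_correlation",
    "cluster_contrasts",
    "top_regulated_union",
]


@dataclass
class FoldChangeMatrix:
    """Genes x contrasts matrix of log2 fold changes, restricted to genes
    significant at alpha in at least one contrast.  ``provenance`` records,
    per retained gene, which contrasts made it significant."""

    values: pd.DataFrame
    provenance: dict[str, list[str]]
    alpha: float

    @property
    def empty(self) -> bool:
        return self.values.shape[0] == 0


def build_foldchange_matrix(de_tables: dict[str, pd.DataFrame], alpha: float = 1e-3) -> FoldChangeMatrix:
    """Union-of-significant fold-change matrix across contrasts."""
    if len(de_tables) < 2:
        raise ValueError("need at least 2 contrasts")
    names = sorted(de_tables)
    universe = de_tables[names[0]].index
    for name in names[1:]:
        if not de_tables[name].index.equals(universe):
            raise ValueError(f"contrast {name!r} has a different gene universe")

    provenance: dict[str, list[str]] = {}
    for name in names:
        table = de_tables[name]
        sig = table.index[table["p"] < alpha]
        for g in sig:
            provenance.setdefault(g, []).append(name)
    retained = [g for g in universe if g in provenance]
    values = pd.DataFrame(
        {name: de_tables[name].loc[retained, "log2fc"] for name in names},
        index=pd.Index(retained, name=universe.name),
    )
    return FoldChangeMatrix(values=values, provenance=provenance, alpha=alpha)


def pairwise_phenotype_correlation(fc: FoldChangeMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation (and two-sided p) between every pair of contrasts
    over the retained genes.  Diagonal r = 1, p = 0."""
    X = fc.values
    if X.shape[0] < 3:
        raise ValueError("need at least 3 retained genes")
    if (X.std(axis=0, ddof=0) == 0).any():
        bad = X.columns[X.std(axis=0, ddof=0) == 0].tolist()
        raise ValueError(f"zero-variance contrast(s): {bad}")
    cols = X.columns
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, ci in enumerate(cols):
        for cj in cols[i + 1:]:
            res = stats.pearsonr(X[ci], X[cj])
            r.loc[ci, cj] = r.loc[cj, ci] = res.statistic
            p.loc[ci, cj] = p.loc[cj, ci] = res.pvalue
    return r, p


def cluster_contrasts(fc: FoldChangeMatrix) -> tuple[np.ndarray, list[str]]:
    """Average-linkage hierarchical clustering of contrasts on distance 1 - r.

    Columns are sorted by label before clustering so the result does not
    depend on input order.  Returns (scipy linkage matrix, leaf labels in
    dendrogram order).
    """
    if fc.values.shape[1] < 2:
        raise ValueError("need at least 2 contrasts")
    ordered = FoldChangeMatrix(fc.values[sorted(fc.values.columns)], fc.provenance, fc.alpha)
    r, _ = pairwise_phenotype_correlation(ordered)
    dist = 1.0 - r.to_numpy()
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    leaves = hierarchy.leaves_list(Z)
    return Z, [ordered.values.columns[i] for i in leaves]


def top_regulated_union(de_a: pd.DataFrame, de_b: pd.DataFrame, k: int = 100) -> list[str]:
    """Union of each contrast's k most strongly regulated genes.

    "Most regulated" is ranked by |log2fc| (descending); ties broken by
    smaller p, then lexicographic gene id.  If k exceeds the universe the
    whole universe is returned.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not de_a.index.equals(de_b.index):
        raise ValueError("contrasts must share a gene universe")

    def top_k(table: pd.DataFrame) -> set[str]:
        order = sorted(
            table.index,
            key=lambda g: (-abs(table.at[g, "log2fc"]), table.at[g, "p"], g),
        )
        return set(order[:k])

    union = top_k(de_a) | top_k(de_b)
    return sorted(union)
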
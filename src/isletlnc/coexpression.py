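"""Weighted co-expression network analysis: modules from topological overlap.

Across a panel of islet samples, genes sharing regulatory inputs co-vary.
The network is built the classic way: gene-gene Pearson correlation is
raised to a soft-thresholding power beta (chosen by the scale-free fit
criterion) to give an adjacency in [0, 1]; the topological overlap measure
(TOM) then rewards gene pairs that share network neighbours; average-linkage
clustering on 1 - TOM with a static tree cut yields modules, summarized by
their eigengene (first principal component of the standardized module
submatrix).  Modules are annotated by hypergeometric enrichment for gene
labels such as lncRNA, enhancer-cluster-associated, or islet TF.

The static cut (rather than a dynamic hybrid cut) is a deliberate choice:
it keeps module detection a pure function of the merge heights and hence
checkable against a brute-force agglomeration oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .enrichment import GeneSetCollection, hypergeometric_enrichment

logger = logging.getLogger(__name__)

__all__ = [
    "CoexpressionResult",
    "pick_soft_threshold",
    "adjacency",
    "topological_overlap",
    "detect_modules",
    "module_eigengene",
    "module_annotation_enrichment",
    "build_network",
]

UNASSIGNED = "unassigned"


@dataclass
class CoexpressionResult:
    beta: float
    tom: pd.DataFrame
    modules: pd.Series  # gene -> module label or "unassigned"
    eigengenes: pd.DataFrame  # module x samples
    major_module_min_size: int = 100

    @property
    def major_modules(self) -> list[str]:
        sizes = self.modules[self.modules != UNASSIGNED].value_counts()
        return sorted(sizes.index[sizes > self.major_module_min_size],
                      key=lambda m: int(m.lstrip("M")))


def _scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log10 p(k) vs log10 k regression.

    Positive slope (not scale-free-like) flips the sign, mirroring the
    usual signed scale-free topology fit index.
    """
    k = connectivity[connectivity > 0]
    if k.size < 2:
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    log_k, log_p = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        log_k.append(np.log10(k[mask].mean()))
        log_p.append(np.log10(mask.sum() / k.size))
    if len(log_k) < 3:
        return 0.0
    slope, _, r, _, _ = stats.linregress(log_k, log_p)
    return float(r**2 * (1.0 if slope < 0 else -1.0))


def pick_soft_threshold(
    expr: pd.DataFrame,
    candidate_powers=(1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16),
    r2_target: float = 0.8,
    mode: str = "unsigned",
) -> float:
    """Smallest candidate power whose signed scale-free fit reaches
    ``r2_target``; falls back to the power maximizing the fit (logged).

    Constant genes carry no correlation signal and are dropped with a
    warning before the correlation matrix is formed.
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    powers = sorted(candidate_powers)
    if powers[0] < 1:
        raise ValueError("powers must be >= 1")
    keep = expr.std(axis=1) > 0
    if not keep.all():
        logger.warning("dropping %d constant genes", int((~keep).sum()))
        expr = expr.loc[keep]
    cor = np.corrcoef(expr.to_numpy(dtype=float))
    fits = {}
    for beta in powers:
        A = _adjacency_array(cor, beta, mode)
        fits[beta] = _scale_free_fit(A.sum(axis=0))
        if fits[beta] >= r2_target:
            return float(beta)
    best = max(fits, key=lambda b: (fits[b], -b))
    logger.info("no power reached R^2 >= %.2f; using best fit beta=%s (R^2=%.3f)",
                r2_target, best, fits[best])
    return float(best)


def _adjacency_array(cor: np.ndarray, beta: float, mode: str) -> np.ndarray:
    if mode == "unsigned":
        A = np.abs(cor) ** beta
    elif mode == "signed":
        A = ((1.0 + cor) / 2.0) ** beta
    else:
        raise ValueError(f"unknown mode {mode!r}")
    np.fill_diagonal(A, 0.0)
    return A


def adjacency(cor_matrix: pd.DataFrame | np.ndarray, beta: float, mode: str = "unsigned"):
    """Soft-threshold adjacency: |r|^beta (unsigned) or ((1+r)/2)^beta (signed).

    The diagonal is zeroed so row sums are network connectivities.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    cor = np.asarray(cor_matrix, dtype=float) if not isinstance(cor_matrix, pd.DataFrame) else cor_matrix.to_numpy(dtype=float)
    if cor.shape[0] != cor.shape[1] or not np.allclose(cor, cor.T, atol=1e-10):
        raise ValueError("correlation matrix must be square and symmetric")
    if np.nanmax(np.abs(cor)) > 1 + 1e-9:
        raise ValueError("correlations must lie in [-1, 1]")
    A = _adjacency_array(cor, beta, mode)
    if isinstance(cor_matrix, pd.DataFrame):
        return pd.DataFrame(A, index=cor_matrix.index, columns=cor_matrix.columns)
    return A


def topological_overlap(A: pd.DataFrame | np.ndarray):
    """Topological overlap matrix.

    TOM_ij = (sum_u A_iu A_uj + A_ij) / (min(k_i, k_j) + 1 - A_ij) off the
    diagonal, with connectivity k_i = sum_u A_iu; TOM_ii = 1.
    """
    labels = A.index if isinstance(A, pd.DataFrame) else None
    A_ = np.asarray(A, dtype=float)
    if (A_ < 0).any():
        raise ValueError("adjacency entries must be non-negative")
    if np.abs(np.diag(A_)).max() > 1e-12:
        raise ValueError("adjacency diagonal must be zero")
    k = A_.sum(axis=0)
    L = A_ @ A_
    denom = np.minimum.outer(k, k) + 1.0 - A_
    tom = (L + A_) / denom
    np.fill_diagonal(tom, 1.0)
    if labels is not None:
        return pd.DataFrame(tom, index=labels, columns=labels)
    return tom


def detect_modules(
    tom: pd.DataFrame,
    cut_height: float | None = None,
    min_module_size: int = 30,
) -> pd.Series:
    """Static tree cut of average-linkage clustering on 1 - TOM.

    Clusters below ``min_module_size`` become "unassigned"; the rest are
    renamed M1, M2, ... by decreasing size (ties by earlier appearance).
    Default cut height is 99% of the largest merge height.
    """
    dist = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    if cut_height is None:
        cut_height = 0.99 * float(Z[:, 2].max())
    if not 0 < cut_height <= 1:
        raise ValueError("cut_height must be in (0, 1]")
    raw = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
    counts = pd.Series(raw).value_counts()
    big = counts.index[counts.to_numpy() >= min_module_size]
    order = sorted(big, key=lambda c: (-counts[c], c))
    rename = {c: f"M{i + 1}" for i, c in enumerate(order)}
    labels = [rename.get(c, UNASSIGNED) for c in raw]
    return pd.Series(labels, index=tom.index, name="module")


def module_eigengene(expr: pd.DataFrame, module_genes: list[str]) -> pd.Series:
    """First principal component of the z-scored module submatrix.

    The sign is oriented so the eigengene correlates positively with the
    average member gene.
    """
    genes = list(module_genes)
    if len(genes) < 2:
        raise ValueError("module needs at least 2 genes")
    X = expr.loc[genes].to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=0)
    if (sd == 0).any():
        raise ValueError("constant gene rows in module")
    Z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    eig = Vt[0]
    if U[:, 0].mean() < 0:
        eig = -eig
    return pd.Series(eig, index=expr.columns, name="eigengene")


def module_annotation_enrichment(
    modules: pd.Series,
    sets: GeneSetCollection,
    alpha: float = 1e-2,
) -> pd.DataFrame:
    """Hypergeometric enrichment of every (module, label set) pair.

    The universe is the clustered gene list.  Empty modules are skipped
    with a log line.  enriched == (p < alpha).
    """
    universe = set(modules.index)
    rows = []
    module_names = sorted(set(modules) - {UNASSIGNED},
                          key=lambda m: int(m.lstrip("M")) if m.lstrip("M").isdigit() else 1 << 30)
    for mod in module_names:
        members = set(modules.index[modules == mod])
        if not members:
            logger.info("module %s empty; skipped", mod)
            continue
        for name in sorted(sets.sets):
            annot = sets[name] & universe
            k = len(members & annot)
            p = hypergeometric_enrichment(members, annot, universe)
            rows.append({"module": mod, "set": name, "module_size": len(members),
                         "set_size": len(annot), "overlap": k, "p": p,
                         "enriched": p < alpha})
    return pd.DataFrame(rows)


def build_network(
    expr: pd.DataFrame,
    beta: float | None = None,
    mode: str = "unsigned",
    cut_height: float | None = None,
    min_module_size: int = 30,
    major_module_min_size: int = 100,
) -> CoexpressionResult:
    """End-to-end network construction: correlation -> adjacency -> TOM ->
    modules -> eigengenes."""
    keep = expr.std(axis=1) > 0
    if not keep.all():
        logger.warning("dropping %d constant genes", int((~keep).sum()))
        expr = expr.loc[keep]
    if beta is None:
        beta = pick_soft_threshold(expr, mode=mode)
    cor = pd.DataFrame(np.corrcoef(expr.to_numpy(dtype=float)),
                       index=expr.index, columns=expr.index)
    A = adjacency(cor, beta, mode)
    tom = topological_overlap(A)
    modules = detect_modules(tom, cut_height=cut_height, min_module_size=min_module_size)
    eig = {}
    for mod in sorted(set(modules) - {UNASSIGNED}, key=lambda m: int(m.lstrip("M"))):
        eig[mod] = module_eigengene(expr, list(modules.index[modules == mod]))
    eigengenes = pd.DataFrame(eig).T if eig else pd.DataFrame(columns=expr.columns)
    return CoexpressionResult(beta=beta, tom=tom, modules=modules,
                              eigengenes=eigengenes,
                              major_module_min_size=major_module_min_size)
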
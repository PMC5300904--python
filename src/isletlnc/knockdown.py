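"""Per-target differential expression and the combinatorial control-split null.

A knockdown screen transduces beta cells with target-specific artificial
microRNAs (amiRNAs) alongside several non-targeting control amiRNAs.  For
each target we pool its amiRNA replicates and test every gene against the
pooled controls with a two-group one-way ANOVA (equivalent to a pooled
t-test).  Because RNAi can deregulate genes non-specifically, the screen's
specificity is judged against a combinatorial null: every 2-vs-3 split of
the control amiRNA groups defines a pseudo-contrast whose DE-gene count
calibrates what "no specific effect" looks like; a real target's pair of
amiRNAs compared against every control triple should yield stochastically
larger counts (one-sided Mann-Whitney).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KnockdownDesign",
    "SpecificityResult",
    "anova_de",
    "enumerate_control_partitions",
    "specificity_null",
    "run_specificity",
    "mann_whitney_one_sided",
]


@dataclass
class KnockdownDesign:
    """Sample layout of a knockdown screen.

    targets maps each target name to its amiRNA groups, each group being the
    list of replicate sample ids transduced with one amiRNA hairpin.
    controls is the list of non-targeting amiRNA groups (typically five).
    """

    targets: dict[str, list[list[str]]]
    controls: list[list[str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, groups in list(self.targets.items()) + [("__controls__", self.controls)]:
            for group in groups:
                if not group:
                    raise ValueError(f"empty replicate group under {name!r}")
                overlap = seen.intersection(group)
                if overlap:
                    raise ValueError(f"sample ids shared across groups: {sorted(overlap)}")
                seen.update(group)

    def target_samples(self, target: str) -> list[str]:
        return [s for group in self.targets[target] for s in group]

    def control_samples(self, indices=None) -> list[str]:
        groups = self.controls if indices is None else [self.controls[i] for i in indices]
        return [s for group in groups for s in group]

    def to_dict(self) -> dict:
        return {"targets": self.targets, "controls": self.controls}

    @classmethod
    def from_dict(cls, d: dict) -> "KnockdownDesign":
        return cls(targets={k: [list(g) for g in v] for k, v in d["targets"].items()},
                   controls=[list(g) for g in d["controls"]])


@dataclass
class SpecificityResult:
    """Outcome of the combinatorial specificity null for one target."""

    target: str
    control_counts: list[int]
    target_counts: list[int]
    mw_p: float
    control_median: float = field(init=False)
    control_iqr: tuple[float, float] = field(init=False)

    def __post_init__(self) -> None:
        cc = np.asarray(self.control_counts, dtype=float)
        self.control_median = float(np.median(cc))
        self.control_iqr = (float(np.percentile(cc, 25)), float(np.percentile(cc, 75)))


def anova_de(
    expr: pd.DataFrame,
    target_samples: list[str],
    control_samples: list[str],
    alpha: float = 1e-3,
) -> pd.DataFrame:
    """Per-gene two-group one-way ANOVA on a log2 expression matrix.

    For each gene the pooled target replicates are compared with the pooled
    control replicates by the one-way F test with (1, nA+nB-2) degrees of
    freedom, which for two groups equals the square of the equal-variance
    pooled t statistic.  Returns a table with columns ``log2fc`` (mean
    target minus mean control), ``F``, ``p`` and ``significant`` (p < alpha).

    Genes that are constant everywhere (zero between- and within-group
    variance) get F = 0, p = 1.  Genes with zero within-group variance but
    distinct group means get p = 0.
    """
    target_samples = list(target_samples)
    control_samples = list(control_samples)
    if len(target_samples) < 2 or len(control_samples) < 2:
        raise ValueError("need at least 2 samples per side")
    overlap = set(target_samples) & set(control_samples)
    if overlap:
        raise ValueError(f"samples in both groups: {sorted(overlap)}")
    missing = (set(target_samples) | set(control_samples)) - set(expr.columns)
    if missing:
        raise ValueError(f"samples absent from matrix: {sorted(missing)}")

    A = expr[target_samples].to_numpy(dtype=float)
    B = expr[control_samples].to_numpy(dtype=float)
    na, nb = A.shape[1], B.shape[1]
    ma, mb = A.mean(axis=1), B.mean(axis=1)
    ss_within = ((A - ma[:, None]) ** 2).sum(axis=1) + ((B - mb[:, None]) ** 2).sum(axis=1)
    dof = na + nb - 2
    diff = ma - mb
    se2 = (ss_within / dof) * (1.0 / na + 1.0 / nb)

    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(se2 > 0, diff**2 / se2, np.where(diff == 0, 0.0, np.inf))
    p = np.where(np.isinf(F), 0.0, stats.f.sf(np.where(np.isinf(F), 1.0, F), 1, dof))
    p = np.where((se2 == 0) & (diff == 0), 1.0, p)

    return pd.DataFrame(
        {"log2fc": diff, "F": F, "p": p, "significant": p < alpha},
        index=expr.index,
    )


def enumerate_control_partitions(control_groups: list) -> list[tuple[tuple, tuple]]:
    """All 2-vs-3 style splits of the control groups.

    Returns every unordered 2-subset paired with its complement, in
    lexicographic order of the 2-subset's positions: C(n, 2) partitions for
    n control groups (10 for the canonical five).
    """
    groups = list(control_groups)
    if len(groups) < 3:
        raise ValueError("need at least 3 control groups to form 2-vs-3 splits")
    out = []
    for pair_idx in itertools.combinations(range(len(groups)), 2):
        rest = tuple(i for i in range(len(groups)) if i not in pair_idx)
        out.append((tuple(groups[i] for i in pair_idx), tuple(groups[i] for i in rest)))
    return out


def specificity_null(
    expr: pd.DataFrame,
    design: KnockdownDesign,
    target: str,
    alpha: float = 1e-3,
) -> SpecificityResult:
    """Combinatorial control-split specificity test for one target.

    control_counts: DE-gene counts from every 2-vs-3 partition of the
    control amiRNA groups (pooled pair vs pooled triple).  target_counts:
    DE counts of the target's fixed amiRNA pair against every 3-subset of
    control groups.  mw_p: one-sided exact Mann-Whitney p for the
    alternative that target counts are stochastically larger.
    """
    groups = design.targets.get(target)
    if groups is None:
        raise KeyError(f"unknown target {target!r}")
    if len(groups) != 2:
        raise ValueError(
            f"target {target!r} has {len(groups)} amiRNA groups; the specificity "
            "null is defined only for targets with exactly 2"
        )
    n_ctrl = len(design.controls)
    if n_ctrl < 3:
        raise ValueError("need at least 3 control groups")

    control_counts = []
    for pair, triple in enumerate_control_partitions(list(range(n_ctrl))):
        de = anova_de(expr, design.control_samples(pair), design.control_samples(triple), alpha)
        control_counts.append(int(de["significant"].sum()))

    target_pool = design.target_samples(target)
    target_counts = []
    for triple in itertools.combinations(range(n_ctrl), 3):
        de = anova_de(expr, target_pool, design.control_samples(triple), alpha)
        target_counts.append(int(de["significant"].sum()))

    mw_p = mann_whitney_one_sided(control_counts, target_counts)
    return SpecificityResult(target, control_counts, target_counts, mw_p)


def run_specificity(
    expr: pd.DataFrame,
    design: KnockdownDesign,
    alpha: float = 1e-3,
) -> tuple[dict[str, SpecificityResult], dict[str, str]]:
    """Specificity null for every eligible target; ineligible ones are skipped.

    Mirrors the screen's restriction to targets with exactly two validated
    amiRNAs.  Returns (results, skipped-with-reason).
    """
    results: dict[str, SpecificityResult] = {}
    skipped: dict[str, str] = {}
    for target, groups in design.targets.items():
        if len(groups) != 2:
            skipped[target] = f"{len(groups)} amiRNA groups (need exactly 2)"
            continue
        results[target] = specificity_null(expr, design, target, alpha)
    return results, skipped


_EXACT_LIMIT = 20


def mann_whitney_one_sided(a, b) -> float:
    """One-sided Mann-Whitney p-value for "b stochastically greater than a".

    For combined sample size <= 20 the p-value is exact: all C(n+m, m)
    assignments of the pooled mid-ranks to the second sample are enumerated,
    which handles ties correctly under the permutation null.  Larger samples
    use the normal approximation with tie correction and continuity
    correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    r_obs = ranks[n:].sum()

    if n + m <= _EXACT_LIMIT:
        # count rank assignments by dynamic programming over the doubled
        # mid-ranks (always integers), equivalent to full enumeration of the
        # C(n+m, m) subsets but polynomial time
        scaled = np.rint(2 * ranks).astype(np.int64)
        target = int(np.rint(2 * r_obs))
        total_sum = int(scaled.sum())
        dp = np.zeros((m + 1, total_sum + 1))
        dp[0, 0] = 1.0
        for v in scaled:
            for c in range(m, 0, -1):
                dp[c, v:] += dp[c - 1, : total_sum + 1 - v]
        hits = dp[m, target:].sum()
        return float(hits / math.comb(n + m, m))

    res = stats.mannwhitneyu(b, a, alternative="greater", method="asymptotic")
    return float(res.pvalue)
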
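"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators emulate the study's data types:

* a knockdown screen: log2 array-like intensities for targets transduced
  with one or two amiRNAs (duplicate/triplicate replicates) next to five
  non-targeting control amiRNA groups; each target silences a planted
  regulon and its own transcript (>= 50% knockdown);
* an islet cohort: a latent-factor model x_gj = lambda_g * f_m(g),j + eps
  over 64 samples producing co-expression modules, with lncRNA/TF biotype
  labels and adjacent cis-pairs driven by a shared pair factor;
* a case/control count cohort: negative-binomial counts with per-sample
  depth factors and planted log2 effects, mirroring a 50-control vs
  10-15-case islet RNA-seq design.

Defaults follow the screen's published design (five controls, two amiRNAs
per target, triplicates, 64 cohort samples).  The replicate noise of the
arrays is not published; 0.25 log2 units is used as a realistic
technical+biological spread for a clonal beta-cell line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .knockdown import KnockdownDesign

__all__ = [
    "TargetSpec",
    "KnockdownSimConfig",
    "CohortSimConfig",
    "CountSimConfig",
    "GroundTruth",
    "simulate_knockdown_experiment",
    "simulate_islet_cohort",
    "simulate_count_cohort",
]


@dataclass
class TargetSpec:
    """One knockdown target: its amiRNA count, planted regulon and effects.

    ``effect`` is the log2 shift of each regulon gene in the target's
    samples: a scalar applies uniformly, a list is aligned with ``regulon``
    (real knockdowns dysregulate genes in both directions, so mixed-sign
    lists are the realistic choice).
    """

    name: str
    regulon: list[int]
    effect: float | list[float]
    n_amirnas: int = 2
    self_index: int | None = None  # gene row representing the target transcript
    self_effect: float = -1.5  # >= 50% knockdown of the target itself

    def __post_init__(self) -> None:
        if self.n_amirnas not in (1, 2):
            raise ValueError("n_amirnas must be 1 or 2")
        if isinstance(self.effect, (list, tuple)) and len(self.effect) != len(self.regulon):
            raise ValueError("per-gene effect list must align with the regulon")
        if self.self_index is not None and self.self_effect > -1.0:
            raise ValueError("self_effect must be <= -1 log2 (>= 50% knockdown)")

    def effect_map(self) -> dict[int, float]:
        if isinstance(self.effect, (list, tuple)):
            return {int(g): float(e) for g, e in zip(self.regulon, self.effect)}
        return {int(g): float(self.effect) for g in self.regulon}


@dataclass
class KnockdownSimConfig:
    n_genes: int
    targets: list[TargetSpec]
    n_controls: int = 5
    replicates_per_amirna: int = 3
    noise_sd: float = 0.25
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    shared_regulon_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_controls < 2:
            raise ValueError("need at least 2 control groups for the specificity null")
        names = [t.name for t in self.targets]
        if len(set(names)) != len(names):
            raise ValueError("duplicate target names")
        for t in self.targets:
            idx = list(t.regulon) + ([t.self_index] if t.self_index is not None else [])
            if any(not 0 <= i < self.n_genes for i in idx):
                raise ValueError(f"regulon index out of range for target {t.name!r}")
        for a, b, frac in self.shared_regulon_pairs:
            if not 0.0 <= frac <= 1.0:
                raise ValueError("overlap fraction must be in [0, 1]")
            if a not in names or b not in names:
                raise ValueError(f"unknown target in shared pair ({a!r}, {b!r})")


@dataclass
class CohortSimConfig:
    n_genes: int
    n_samples: int = 64
    module_sizes: list[int] = field(default_factory=lambda: [150, 150, 120, 120])
    loading_mean: float = 1.0
    loading_sd: float = 0.0
    noise_sd: float = 1.0
    lncrna_fraction: float | list[float] = 0.15
    tf_fraction: float | list[float] = 0.05
    cis_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    chrom_length: int = 500_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module sizes exceed n_genes")
        used = set()
        for lnc, cod, w in self.cis_pairs:
            if not (0 <= lnc < self.n_genes and 0 <= cod < self.n_genes) or lnc == cod:
                raise ValueError("invalid cis-pair indices")
            if not 0.0 < w <= 1.0:
                raise ValueError("shared-factor weight must be in (0, 1]")
            if {lnc, cod} & used:
                raise ValueError("gene reused across cis pairs")
            used.update((lnc, cod))

    def fraction(self, attr: str, module: int) -> float:
        value = getattr(self, attr)
        return value[module] if isinstance(value, (list, tuple)) else value


@dataclass
class CountSimConfig:
    n_genes: int
    n_control: int = 50
    n_case: int = 15
    mean_log_mu: float = 5.0
    sd_log_mu: float = 1.5
    dispersion_shape: float = 2.0
    dispersion_scale: float = 0.05
    depth_factors: list[float] | None = None
    de_genes: dict[int, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion_shape <= 0 or self.dispersion_scale <= 0:
            raise ValueError("dispersion parameters must be positive")
        if self.depth_factors is not None:
            if len(self.depth_factors) != self.n_control + self.n_case:
                raise ValueError("one depth factor per sample required")
            if any(d <= 0 for d in self.depth_factors):
                raise ValueError("depth factors must be positive")
        if any(not 0 <= g < self.n_genes for g in self.de_genes):
            raise ValueError("DE gene index out of range")


@dataclass
class GroundTruth:
    """Planted structure of a simulated dataset (whatever fields apply)."""

    regulons: dict[str, list[int]] = field(default_factory=dict)
    regulon_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    self_indices: dict[str, int] = field(default_factory=dict)
    modules: dict[str, list[str]] = field(default_factory=dict)
    factors: pd.DataFrame | None = None
    cis_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    de_effects: dict[str, float] = field(default_factory=dict)
    size_factors: pd.Series | None = None

    def module_labels(self, gene_ids: list[str]) -> pd.Series:
        lookup = {g: m for m, genes in self.modules.items() for g in genes}
        return pd.Series([lookup.get(g, "none") for g in gene_ids], index=gene_ids)


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def _apply_shared_regulons(
    config: KnockdownSimConfig, rng: np.random.Generator
) -> dict[str, dict[int, float]]:
    """Resolve per-target effect maps after imposing the declared overlaps.

    For a pair (A, B, frac), a fraction ``frac`` of B's regulon is replaced
    by genes drawn from A's regulon, giving |overlap| ~ frac * |B|; the
    shared genes keep A's effect in both targets (a shared program moves
    the same genes the same way).
    """
    effects = {t.name: t.effect_map() for t in config.targets}
    for a, b, frac in config.shared_regulon_pairs:
        ea, eb = effects[a], effects[b]
        n_shared = min(int(round(frac * len(eb))), len(ea))
        shared = [int(g) for g in rng.choice(sorted(ea), size=n_shared, replace=False)]
        keep = [g for g in sorted(eb) if g not in set(shared)][: len(eb) - n_shared]
        effects[b] = {**{g: eb[g] for g in keep}, **{g: ea[g] for g in shared}}
    return effects


def simulate_knockdown_experiment(
    config: KnockdownSimConfig,
) -> tuple[pd.DataFrame, KnockdownDesign, GroundTruth]:
    """Log2 expression matrix + design + ground truth for a knockdown screen.

    Matrix = per-gene baseline + planted regulon effect in the target's
    samples (plus the target transcript's own knockdown) + iid Gaussian
    noise.  Sample ids encode group and replicate; controls are ``ctrlK_rJ``.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)
    effect_maps = _apply_shared_regulons(config, rng)

    columns: list[str] = []
    col_effect: list[np.ndarray] = []
    targets_design: dict[str, list[list[str]]] = {}
    for t in config.targets:
        shift = np.zeros(config.n_genes)
        for g, e in effect_maps[t.name].items():
            shift[g] += e
        if t.self_index is not None:
            shift[t.self_index] += t.self_effect
        groups = []
        for a in range(t.n_amirnas):
            group = []
            for r in range(config.replicates_per_amirna):
                name = f"{t.name}_ami{a + 1}_r{r + 1}"
                group.append(name)
                columns.append(name)
                col_effect.append(shift)
            groups.append(group)
        targets_design[t.name] = groups

    control_groups = []
    zero = np.zeros(config.n_genes)
    for c in range(config.n_controls):
        group = []
        for r in range(config.replicates_per_amirna):
            name = f"ctrl{c + 1}_r{r + 1}"
            group.append(name)
            columns.append(name)
            col_effect.append(zero)
        control_groups.append(group)

    effects = np.column_stack(col_effect)
    noise = rng.normal(0.0, config.noise_sd, size=effects.shape) if config.noise_sd > 0 else 0.0
    values = baseline[:, None] + effects + noise
    expr = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=columns)
    design = KnockdownDesign(targets=targets_design, controls=control_groups)
    truth = GroundTruth(
        regulons={name: sorted(emap) for name, emap in effect_maps.items()},
        regulon_effects={name: {genes[g]: e for g, e in emap.items()}
                         for name, emap in effect_maps.items()},
        self_indices={t.name: t.self_index for t in config.targets if t.self_index is not None},
    )
    return expr, design, truth


def simulate_islet_cohort(
    config: CohortSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Latent-factor cohort matrix + BED-style annotation + ground truth.

    Module genes follow x = lambda * f_module + noise; declared cis-pairs
    follow x = w * f_pair + sqrt(1 - w^2) * noise_unit so the pair's
    population correlation is w^2.  The annotation places genes along one
    synthetic chromosome with cis-pair members adjacent (2 kb apart inside
    a pair, 50 kb between neighbouring loci).
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_genes, config.n_samples
    genes = _gene_ids(n)
    values = rng.normal(0.0, config.noise_sd, size=(n, m))

    modules: dict[str, list[str]] = {}
    factor_rows = {}
    biotype = np.array(["coding"] * n, dtype=object)
    cis_members = {g for pair in config.cis_pairs for g in pair[:2]}
    free = [i for i in range(n) if i not in cis_members]
    cursor = 0
    for mi, size in enumerate(config.module_sizes):
        name = f"module{mi + 1}"
        members = free[cursor:cursor + size]
        cursor += size
        f = rng.normal(0.0, 1.0, size=m)
        lam = rng.normal(config.loading_mean, config.loading_sd, size=len(members))
        values[members] += lam[:, None] * f[None, :]
        modules[name] = [genes[i] for i in members]
        factor_rows[name] = f
        n_lnc = int(round(config.fraction("lncrna_fraction", mi) * len(members)))
        n_tf = int(round(config.fraction("tf_fraction", mi) * len(members)))
        labelled = rng.permutation(members)
        biotype[labelled[:n_lnc]] = "lncRNA"
        biotype[labelled[n_lnc:n_lnc + n_tf]] = "TF"

    truth_pairs = []
    for pi, (lnc, cod, w) in enumerate(config.cis_pairs):
        h = rng.normal(0.0, 1.0, size=m)
        for idx in (lnc, cod):
            eps = rng.normal(0.0, 1.0, size=m)
            values[idx] = w * h + np.sqrt(1.0 - w * w) * eps
        biotype[lnc] = "lncRNA"
        biotype[cod] = "coding"
        factor_rows[f"cis{pi + 1}"] = h
        truth_pairs.append((genes[lnc], genes[cod], w))

    # placement order: cis pairs first (members adjacent), then the rest
    order: list[int] = []
    for lnc, cod, _ in config.cis_pairs:
        order.extend([min(lnc, cod), max(lnc, cod)])
    order.extend(i for i in range(n) if i not in set(order))
    starts = np.zeros(n, dtype=int)
    pos = 10_000
    pair_next = {order[2 * i]: order[2 * i + 1] for i in range(len(config.cis_pairs))}
    i = 0
    while i < len(order):
        g = order[i]
        starts[g] = pos
        if g in pair_next:  # partner sits 2 kb downstream
            starts[pair_next[g]] = pos + 1_000 + 2_000
            pos = starts[pair_next[g]] + 1_000 + 50_000
            i += 2
        else:
            pos += 1_000 + 50_000
            i += 1
    if pos > config.chrom_length:
        raise ValueError("chrom_length too small for the gene count")

    annot = pd.DataFrame({
        "chrom": "chrSim",
        "start": starts,
        "end": starts + 1_000,
        "strand": "+",
        "gene_id": genes,
        "biotype": biotype,
    }).sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)

    expr = pd.DataFrame(values, index=pd.Index(genes, name="gene"),
                        columns=[f"islet{j + 1:02d}" for j in range(m)])
    factors = pd.DataFrame(factor_rows, index=expr.columns).T
    truth = GroundTruth(modules=modules, factors=factors, cis_pairs=truth_pairs)
    return expr, annot, truth


def simulate_count_cohort(config: CountSimConfig) -> tuple[pd.DataFrame, pd.Series, GroundTruth]:
    """NB count matrix + condition labels + ground truth.

    counts_gj ~ NB(mean = depth_j * mu_g * 2^(effect_g * case_j),
    dispersion alpha_g), sampled as a gamma-Poisson mixture.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    n_samples = config.n_control + config.n_case
    genes = _gene_ids(n)
    samples = [f"ctrl{j + 1:02d}" for j in range(config.n_control)] + \
              [f"case{j + 1:02d}" for j in range(config.n_case)]
    conditions = pd.Series(["control"] * config.n_control + ["case"] * config.n_case,
                           index=samples, name="condition")
    depth = np.asarray(config.depth_factors, dtype=float) if config.depth_factors is not None \
        else np.ones(n_samples)

    mu = rng.lognormal(config.mean_log_mu, config.sd_log_mu, size=n)
    disp = rng.gamma(config.dispersion_shape, config.dispersion_scale, size=n)
    effect = np.zeros(n)
    for g, e in config.de_genes.items():
        effect[g] = e
    case_mask = (conditions == "case").to_numpy()

    mean = depth[None, :] * mu[:, None] * np.power(2.0, effect[:, None] * case_mask[None, :])
    shape = 1.0 / disp
    lam = rng.gamma(shape[:, None], mean * disp[:, None])
    counts = rng.poisson(lam)
    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=samples)
    truth = GroundTruth(
        de_effects={genes[g]: e for g, e in config.de_genes.items()},
        size_factors=pd.Series(depth, index=samples, name="depth"),
    )
    return counts_df, conditions, truth
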
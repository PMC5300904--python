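"""End-to-end orchestration of the analysis stages on one configuration.

``run_pipeline`` executes, in dependency order: knockdown simulation →
per-target differential expression → combinatorial specificity null →
phenotype-similarity analysis → expression-matched GSEA → islet-cohort
simulation → co-expression network and module enrichment → cis-regulatory
scan → count-cohort simulation → size factors and NB differential
expression.  Every stage reads its thresholds from a single resolved
configuration, which is written next to the outputs together with a JSON
report.
"""

from __future__ import annotations

import copy
import json
import logging
from pathlib import Path

import numpy as np


from . import __version__, cis_disease, coexpression, enrichment, knockdown, phenotype
from .enrichment import GeneSetCollection
from .io import provenance_line, write_bed_annotation, write_expression_tsv
from .synthetic import (
    CohortSimConfig,
    CountSimConfig,
    KnockdownSimConfig,
    TargetSpec,
    simulate_count_cohort,
    simulate_islet_cohort,
    simulate_knockdown_experiment,
)

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_CONFIG", "default_knockdown_config", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "alpha_de": 1e-3,          # per-gene DE gate
    "alpha_module": 1e-2,      # module-enrichment gate
    "cis_p_threshold": 1e-7,   # cis-candidate gate
    "disease_alpha": 0.05,     # BH-adjusted disease DE gate
    "efficiency_gate_pct": 50.0,
    "major_module_size": 100,
    "n_control_sets": 10,
    "n_bins": 10,
    "gsea_permutations": 200,
    "knockdown": {
        "n_genes": 2000,
        "n_controls": 5,
        "replicates_per_amirna": 3,
        "noise_sd": 0.25,
        "regulon_size": 120,
        "effect_magnitude": 1.5,
        "overlap_fraction": 0.5,
    },
    "cohort": {
        "n_genes": 600,
        "n_samples": 64,
        "module_sizes": [120, 110, 100, 90],
        "noise_sd": 1.0,
        "lncrna_fraction": [0.35, 0.05, 0.05, 0.05],
        "tf_fraction": [0.03, 0.25, 0.03, 0.03],
        "n_cis_pairs": 10,
        "cis_weight": 0.9,
    },
    "counts": {
        "n_genes": 2000,
        "n_control": 50,
        "n_case": 15,
        "n_de": 100,
        "effect": 2.0,
    },
    "coexpression": {"beta": 6, "min_module_size": 30},
}


def default_knockdown_config(params: dict, seed: int) -> KnockdownSimConfig:
    """Two-target screen (a lncRNA-like and a TF-like regulator) sharing
    half their regulons, next to the five-control design."""
    n_genes = params["n_genes"]
    size = params["regulon_size"]
    rng = np.random.default_rng(seed + 1)
    pool = rng.choice(n_genes - 2, size=2 * size, replace=False) + 2

    def effects() -> list[float]:
        mag = rng.normal(params["effect_magnitude"], 0.3, size=size)
        return list(np.clip(np.abs(mag), 0.5, None) * rng.choice([-1.0, 1.0], size=size))

    t1 = TargetSpec(name="LNC1", regulon=sorted(int(i) for i in pool[:size]),
                    effect=effects(), self_index=0)
    t2 = TargetSpec(name="TF1", regulon=sorted(int(i) for i in pool[size:]),
                    effect=effects(), self_index=1)
    return KnockdownSimConfig(
        n_genes=n_genes,
        targets=[t1, t2],
        n_controls=params["n_controls"],
        replicates_per_amirna=params["replicates_per_amirna"],
        noise_sd=params["noise_sd"],
        shared_regulon_pairs=[("LNC1", "TF1", params["overlap_fraction"])],
        seed=seed,
    )


def run_pipeline(config: dict | None = None, out_dir=None) -> dict:
    """Run every stage on the bundled synthetic scenario; return the report.

    All randomness derives from ``config['seed']``.  When ``out_dir`` is
    given, the resolved configuration, the simulated inputs and the JSON
    report are written there.
    """
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    for key, value in (config or {}).items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    seed = int(cfg["seed"])
    report: dict = {"version": __version__, "seed": seed}

    # --- knockdown screen -------------------------------------------------
    logger.info("stage knockdown: simulating screen")
    kd_cfg = default_knockdown_config(cfg["knockdown"], seed)
    expr, design, kd_truth = simulate_knockdown_experiment(kd_cfg)
    de_tables = {}
    for target in design.targets:
        de_tables[target] = knockdown.anova_de(
            expr, design.target_samples(target), design.control_samples(),
            alpha=cfg["alpha_de"])
    report["knockdown_de"] = {
        t: {"n_significant": int(tab["significant"].sum())} for t, tab in de_tables.items()
    }

    logger.info("stage specificity: control-split null")
    spec_results, skipped = knockdown.run_specificity(expr, design, alpha=cfg["alpha_de"])
    report["specificity"] = {
        t: {"control_median": r.control_median, "control_iqr": r.control_iqr,
            "n_control_comparisons": len(r.control_counts),
            "n_target_comparisons": len(r.target_counts), "mw_p": r.mw_p}
        for t, r in spec_results.items()
    }
    report["specificity"]["skipped"] = skipped

    # --- phenotype similarity --------------------------------------------
    logger.info("stage phenotype: fold-change correlation")
    fc = phenotype.build_foldchange_matrix(de_tables, alpha=cfg["alpha_de"])
    r_mat, p_mat = phenotype.pairwise_phenotype_correlation(fc)
    _, leaf_order = phenotype.cluster_contrasts(fc)
    pair = tuple(de_tables)
    top_union = phenotype.top_regulated_union(de_tables[pair[0]], de_tables[pair[1]], k=100)
    report["phenotype"] = {
        "n_retained_genes": int(fc.values.shape[0]),
        "pairwise_r": r_mat.round(4).to_dict(),
        "leaf_order": leaf_order,
        "top100_union_size": len(top_union),
    }

    # --- enrichment -------------------------------------------------------
    logger.info("stage enrichment: matched-control GSEA")
    focal = de_tables[pair[0]]
    ranked = focal["log2fc"].sort_values(ascending=False)
    # analogue of an enhancer-cluster set: the genes the target downregulates
    target_set = {g for g, e in kd_truth.regulon_effects[pair[0]].items() if e < 0}
    mean_expr = expr.mean(axis=1)
    controls = enrichment.expression_matched_control_sets(
        target_set, mean_expr, n_sets=cfg["n_control_sets"], n_bins=cfg["n_bins"],
        seed=seed + 11)
    es, _ = enrichment.gsea_enrichment_score(ranked, target_set)
    p_gsea, nes = enrichment.gsea_permutation_p(
        ranked, target_set, n_perm=cfg["gsea_permutations"], seed=seed + 12)
    control_es = [enrichment.gsea_enrichment_score(ranked, s)[0] for s in controls]
    report["enrichment"] = {
        "target_es": es, "target_p": p_gsea, "target_nes": nes,
        "control_es": control_es,
        "control_mean_expr_offsets": [
            float(mean_expr.loc[sorted(s)].mean() - mean_expr.loc[sorted(target_set)].mean())
            for s in controls],
    }

    # --- co-expression cohort --------------------------------------------
    logger.info("stage coexpression: module detection")
    co = cfg["cohort"]
    n_pairs = co["n_cis_pairs"]
    total = co["n_genes"]
    pair_idx = [(total - 2 * (i + 1), total - 2 * (i + 1) + 1) for i in range(n_pairs)]
    cohort_cfg = CohortSimConfig(
        n_genes=total, n_samples=co["n_samples"], module_sizes=co["module_sizes"],
        noise_sd=co["noise_sd"],
        lncrna_fraction=co.get("lncrna_fraction", 0.15),
        tf_fraction=co.get("tf_fraction", 0.05),
        cis_pairs=[(a, b, co["cis_weight"]) for a, b in pair_idx],
        seed=seed + 21)
    cohort_expr, annot, cohort_truth = simulate_islet_cohort(cohort_cfg)
    net = coexpression.build_network(
        cohort_expr, beta=cfg["coexpression"]["beta"],
        min_module_size=cfg["coexpression"]["min_module_size"],
        major_module_min_size=cfg["major_module_size"])
    label_sets = GeneSetCollection(
        sets={bt: set(annot.loc[annot["biotype"] == bt, "gene_id"])
              for bt in ("lncRNA", "TF") if (annot["biotype"] == bt).any()},
        universe=set(annot["gene_id"]))
    mod_enrich = coexpression.module_annotation_enrichment(
        net.modules, label_sets, alpha=cfg["alpha_module"])
    report["coexpression"] = {
        "beta": net.beta,
        "n_modules": int((net.modules != coexpression.UNASSIGNED).sum() and
                         len(set(net.modules) - {coexpression.UNASSIGNED})),
        "major_modules": net.major_modules,
        "n_enriched_module_set_pairs": int(mod_enrich["enriched"].sum()) if len(mod_enrich) else 0,
    }

    # --- cis scan ---------------------------------------------------------
    logger.info("stage cis: adjacent-gene correlation scan")
    cis = cis_disease.cis_pair_scan(cohort_expr, annot, p_threshold=cfg["cis_p_threshold"])
    true_pairs = {(l, c) for l, c, _ in cohort_truth.cis_pairs}
    found = {(row["lncRNA"], row["partner"]) for _, row in cis.iterrows() if row["candidate"]}
    recall = len(found & true_pairs) / len(true_pairs) if true_pairs else float("nan")
    report["cis"] = {"n_candidates": int(cis["candidate"].sum()),
                     "n_lncRNAs_scanned": int(len(cis)),
                     "planted_pair_recall": recall}

    # --- disease cohort ---------------------------------------------------
    logger.info("stage disease: NB differential expression")
    ct = cfg["counts"]
    rng = np.random.default_rng(seed + 31)
    de_idx = rng.choice(ct["n_genes"], size=ct["n_de"], replace=False)
    signs = rng.choice([-1.0, 1.0], size=ct["n_de"])
    count_cfg = CountSimConfig(
        n_genes=ct["n_genes"], n_control=ct["n_control"], n_case=ct["n_case"],
        de_genes={int(g): float(s * ct["effect"]) for g, s in zip(de_idx, signs)},
        depth_factors=list(rng.uniform(0.5, 2.0, size=ct["n_control"] + ct["n_case"])),
        seed=seed + 32)
    counts, conditions, count_truth = simulate_count_cohort(count_cfg)
    sf = cis_disease.size_factors(counts)
    disease = cis_disease.nb_wald_de(counts, conditions, sf=sf, alpha=cfg["disease_alpha"])
    true_de = set(count_truth.de_effects)
    called = set(disease.index[disease["significant"].fillna(False)])
    report["disease_de"] = {
        "n_significant": len(called),
        "power_on_planted": len(called & true_de) / len(true_de),
        "size_factor_max_rel_err": float(np.max(np.abs(
            sf / sf.mean() / (count_truth.size_factors / count_truth.size_factors.mean()) - 1))),
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "resolved_config.json", "w") as fh:
            json.dump(cfg, fh, indent=2, default=str)
        write_expression_tsv(expr, out / "knockdown_expr.tsv", cfg)
        write_expression_tsv(cohort_expr, out / "cohort_expr.tsv", cfg)
        write_bed_annotation(annot, out / "cohort_annotation.bed")
        for t, tab in de_tables.items():
            with open(out / f"de_{t}.tsv", "w") as fh:
                fh.write(provenance_line(cfg) + "\n")
                tab.to_csv(fh, sep="\t")
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=str)
    return report
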
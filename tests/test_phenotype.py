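"""Fold-change matrices, phenotype correlation and contrast clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

from isletlnc.knockdown import anova_de
from isletlnc.phenotype import (
    build_foldchange_matrix,
    cluster_contrasts,
    pairwise_phenotype_correlation,
    top_regulated_union,
)
from isletlnc.synthetic import (
    KnockdownSimConfig,
    TargetSpec,
    simulate_knockdown_experiment,
)


def _de_table(genes, log2fc, p):
    return pd.DataFrame({"log2fc": log2fc, "F": 1.0, "p": p,
                         "significant": np.asarray(p) < 1e-3},
                        index=pd.Index(genes, name="gene"))


GENES = [f"g{i}" for i in range(4)]


class TestBuildFoldChangeMatrix:
    def test_empty_when_nothing_significant(self):
        tabs = {"A": _de_table(GENES, [1, 2, 3, 4], [0.5] * 4),
                "B": _de_table(GENES, [0, 0, 0, 0], [0.9] * 4)}
        fc = build_foldchange_matrix(tabs)
        assert fc.empty and fc.values.shape == (0, 2)

    def test_union_semantics_keep_gene_from_single_contrast(self):
        tabs = {"A": _de_table(GENES, [1, 2, 3, 4], [1e-5, 0.5, 0.5, 0.5]),
                "B": _de_table(GENES, [5, 6, 7, 8], [0.5] * 4)}
        fc = build_foldchange_matrix(tabs)
        assert list(fc.values.index) == ["g0"]
        assert fc.values.loc["g0", "B"] == 5  # fold change carried from the other contrast
        assert fc.provenance["g0"] == ["A"]

    def test_mismatched_universe_rejected(self):
        tabs = {"A": _de_table(GENES, [1] * 4, [0.5] * 4),
                "B": _de_table(["x"], [1], [0.5])}
        with pytest.raises(ValueError, match="universe"):
            build_foldchange_matrix(tabs)

    def test_retained_set_is_planted_regulons_plus_false_positives(self):
        rng = np.random.default_rng(0)
        size = 50
        pool = rng.choice(np.arange(2, 1000), size=2 * size, replace=False)
        eff = lambda: list(rng.choice([-1.5, 1.5], size=size))  # noqa: E731
        cfg = KnockdownSimConfig(
            n_genes=1000,
            targets=[
                TargetSpec("A", sorted(int(i) for i in pool[:size]), eff(), self_index=0),
                TargetSpec("B", sorted(int(i) for i in pool[size:]), eff(), self_index=1),
            ],
            shared_regulon_pairs=[("A", "B", 0.5)],
            noise_sd=0.25, seed=4)
        expr, design, truth = simulate_knockdown_experiment(cfg)
        tabs = {t: anova_de(expr, design.target_samples(t), design.control_samples())
                for t in design.targets}
        fc = build_foldchange_matrix(tabs)
        planted = {expr.index[i] for t in truth.regulons for i in truth.regulons[t]}
        planted |= {expr.index[i] for i in truth.self_indices.values()}
        extra = set(fc.values.index) - planted
        missed = planted - set(fc.values.index)
        # nearly all planted genes retained, very few chance positives
        assert len(missed) <= 0.1 * len(planted)
        assert len(extra) <= 10


class TestPairwiseCorrelation:
    def test_self_correlation_is_one(self):
        tabs = {"A": _de_table(GENES, [1.0, 2, 3, 4], [1e-5] * 4),
                "B": _de_table(GENES, [2.0, 4, 5, 4], [1e-5] * 4)}
        r, p = pairwise_phenotype_correlation(build_foldchange_matrix(tabs))
        assert r.loc["A", "A"] == 1.0

    def test_hand_computed_r_and_p(self):
        tabs = {"A": _de_table(GENES, [1.0, 2, 3, 4], [1e-5] * 4),
                "B": _de_table(GENES, [2.0, 4, 5, 4], [1e-5] * 4)}
        r, p = pairwise_phenotype_correlation(build_foldchange_matrix(tabs))
        assert r.loc["A", "B"] == pytest.approx(0.7182, abs=1e-4)
        assert p.loc["A", "B"] == pytest.approx(0.2818, abs=1e-3)

    def test_matrix_properties(self):
        rng = np.random.default_rng(1)
        tabs = {c: _de_table(range(30), rng.normal(size=30), [1e-5] * 30)
                for c in "ABC"}
        r, _ = pairwise_phenotype_correlation(build_foldchange_matrix(tabs))
        assert np.allclose(r, r.T)
        assert np.allclose(np.diag(r), 1.0)
        assert (r.to_numpy() <= 1).all() and (r.to_numpy() >= -1).all()

    def test_correlation_increases_with_regulon_overlap(self):
        """Planted shared-regulon fraction drives phenotype correlation."""
        rng = np.random.default_rng(9)
        size = 60
        rvals = []
        for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
            pool = rng.choice(np.arange(2, 1200), size=2 * size, replace=False)
            eff = list(rng.choice([-1.5, 1.5], size=size))
            cfg = KnockdownSimConfig(
                n_genes=1200,
                targets=[
                    TargetSpec("A", sorted(int(i) for i in pool[:size]), eff, self_index=0),
                    TargetSpec("B", sorted(int(i) for i in pool[size:]),
                               list(rng.choice([-1.5, 1.5], size=size)), self_index=1),
                ],
                shared_regulon_pairs=[("A", "B", frac)],
                noise_sd=0.25, seed=17)
            expr, design, _ = simulate_knockdown_experiment(cfg)
            tabs = {t: anova_de(expr, design.target_samples(t), design.control_samples())
                    for t in design.targets}
            r, _ = pairwise_phenotype_correlation(build_foldchange_matrix(tabs))
            rvals.append(r.loc["A", "B"])
        assert all(b > a for a, b in zip(rvals, rvals[1:]))
        assert abs(rvals[0]) < 0.2 and rvals[-1] > 0.9


class TestClusterContrasts:
    def test_identical_contrasts_merge_first_at_zero(self):
        tabs = {"A": _de_table(GENES, [1.0, 2, 3, 4], [1e-5] * 4),
                "B": _de_table(GENES, [1.0, 2, 3, 4], [1e-5] * 4),
                "C": _de_table(GENES, [4.0, 1, 2, 9], [1e-5] * 4)}
        Z, leaves = cluster_contrasts(build_foldchange_matrix(tabs))
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert {leaves.index("A"), leaves.index("B")} in ({0, 1}, {1, 2})

    def test_merge_order_matches_brute_force_average_linkage(self):
        rng = np.random.default_rng(2)
        tabs = {c: _de_table(range(20), rng.normal(size=20), [1e-5] * 20)
                for c in "ABCD"}
        fc = build_foldchange_matrix(tabs)
        Z, _ = cluster_contrasts(fc)
        # brute-force agglomeration on the same 1 - r distances
        r, _ = pairwise_phenotype_correlation(fc)
        labels = list(r.columns)
        clusters = {i: [i] for i in range(len(labels))}
        d = {(i, j): 1 - r.iloc[i, j] for i in range(4) for j in range(4) if i < j}
        merges = []
        nxt = len(labels)
        while len(clusters) > 1:
            (i, j), h = min(d.items(), key=lambda kv: kv[1])
            merges.append(h)
            merged = clusters.pop(i) + clusters.pop(j)
            newd = {}
            for k, members in clusters.items():
                pairs = [(min(a, b), max(a, b)) for a in merged for b in members]
                # average linkage over original point pairs
                orig = lambda a, b: 1 - r.iloc[a, b]  # noqa: E731
                newd[(min(k, nxt), max(k, nxt))] = np.mean(
                    [orig(*p) for p in [(min(a, b), max(a, b))
                                        for a in merged for b in members]])
            clusters[nxt] = merged
            d = {k: v for k, v in d.items() if not set(k) & {i, j}}
            d.update(newd)
            nxt += 1
        assert np.allclose(sorted(Z[:, 2]), sorted(merges), atol=1e-12)


class TestTopRegulatedUnion:
    def test_identical_tables_union_is_k(self):
        t = _de_table(range(10), np.arange(10, 0, -1.0), [1e-5] * 10)
        assert len(top_regulated_union(t, t, k=4)) == 4

    def test_disjoint_top_sets_union_is_2k(self):
        genes = [f"g{i}" for i in range(10)]
        a = _de_table(genes, [9, 8, 7, 6, 0, 0, 0, 0, 0, 0.0], [1e-5] * 10)
        b = _de_table(genes, [0, 0, 0, 0, 0, 0, 6, 7, 8, 9.0], [1e-5] * 10)
        assert len(top_regulated_union(a, b, k=4)) == 8

    def test_tie_break_by_p_then_id(self):
        genes = ["gB", "gA", "gC", "gD"]
        fc = [2.0, 1.0, 1.0, 1.0]
        a = _de_table(genes, fc, [0.5, 0.3, 0.1, 0.3])
        # exhaustive sort oracle: |fc| desc, then p asc, then id
        oracle = sorted(genes, key=lambda g: (-abs(a.at[g, "log2fc"]), a.at[g, "p"], g))
        assert set(top_regulated_union(a, a, k=2)) == set(oracle[:2]) == {"gB", "gC"}
        assert set(top_regulated_union(a, a, k=3)) == {"gB", "gC", "gA"}

    def test_k_beyond_universe_returns_all(self):
        t = _de_table(range(5), [1, 2, 3, 4, 5.0], [1e-5] * 5)
        assert len(top_regulated_union(t, t, k=50)) == 5
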
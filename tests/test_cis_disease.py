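"""Nearest-gene pairing, cohort correlation scan, size factors and NB DE."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from isletlnc.cis_disease import (
    bh_adjust,
    cis_pair_scan,
    correlation_pvalue,
    nb_wald_de,
    nearest_coding_gene,
    size_factors,
)
from isletlnc.synthetic import (
    CohortSimConfig,
    CountSimConfig,
    simulate_count_cohort,
    simulate_islet_cohort,
)


def _annot(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand",
                                       "gene_id", "biotype"])


class TestNearestCodingGene:
    def test_single_candidate_within_window(self):
        annot = _annot([("chr1", 1000, 2000, "+", "lnc1", "lncRNA"),
                        ("chr1", 12000, 13000, "+", "pc1", "coding")])
        partner = nearest_coding_gene("lnc1", annot)
        assert partner["gene_id"] == "pc1" and partner["distance"] == 10000

    def test_equidistant_tie_prefers_five_prime_side(self):
        annot = _annot([("chr1", 10000, 11000, "+", "lnc1", "lncRNA"),
                        ("chr1", 5000, 6000, "+", "up", "coding"),
                        ("chr1", 15000, 16000, "+", "down", "coding")])
        # both 4 kb away; '+' strand lncRNA -> 5' side is the lower-coordinate gene
        assert nearest_coding_gene("lnc1", annot)["gene_id"] == "up"
        annot_minus = annot.copy()
        annot_minus.loc[0, "strand"] = "-"
        assert nearest_coding_gene("lnc1", annot_minus)["gene_id"] == "down"

    def test_matches_exhaustive_scan_on_crafted_chromosome(self):
        annot = _annot([
            ("chr2", 100, 300, "+", "lncA", "lncRNA"),
            ("chr2", 400, 600, "+", "c1", "coding"),
            ("chr2", 250, 380, "-", "c2", "TF"),
            ("chr2", 5000, 5100, "+", "c3", "coding"),
            ("chr3", 90, 310, "+", "c4", "coding"),
            ("chr2", 10, 60, "-", "c5", "coding"),
        ])
        lnc = annot.iloc[0]
        dists = {}
        for _, row in annot.iterrows():
            if row["biotype"] == "lncRNA" or row["chrom"] != "chr2":
                continue
            dists[row["gene_id"]] = max(0, max(lnc["start"], row["start"])
                                        - min(lnc["end"], row["end"]))
        expected = min(sorted(dists), key=lambda g: dists[g])
        assert nearest_coding_gene("lncA", annot)["gene_id"] == expected == "c2"

    def test_missing_lncrna(self):
        with pytest.raises(KeyError):
            nearest_coding_gene("nope", _annot([("chr1", 0, 1, "+", "a", "coding")]))

    def test_window_excludes_distant_gene(self):
        annot = _annot([("chr1", 0, 100, "+", "lnc1", "lncRNA"),
                        ("chr1", 5_000_000, 5_000_100, "+", "far", "coding")])
        assert nearest_coding_gene("lnc1", annot) is None


class TestCorrelationPvalue:
    def test_perfect_correlation(self):
        r, p = correlation_pvalue([1, 2, 3, 4], [2, 4, 6, 8])
        assert r == 1.0 and p == 0.0

    def test_zero_correlation_gives_p_one(self):
        r, p = correlation_pvalue([1.0, -1.0, 1.0, -1.0], [1.0, 1.0, -1.0, -1.0])
        assert r == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_shared_hand_computed_example(self):
        r, p = correlation_pvalue([1, 2, 3, 4], [2, 4, 5, 4])
        assert r == pytest.approx(0.7182, abs=1e-4)
        assert p == pytest.approx(0.2818, abs=1e-3)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlation_pvalue([1, 1, 1], [1, 2, 3])


class TestCisPairScan:
    def test_planted_pairs_recalled(self):
        pairs = [(100 + 2 * i, 101 + 2 * i, 0.9) for i in range(10)]
        cfg = CohortSimConfig(n_genes=200, n_samples=64, module_sizes=[50],
                              cis_pairs=pairs, seed=3)
        expr, annot, truth = simulate_islet_cohort(cfg)
        table = cis_pair_scan(expr, annot)
        hits = {(row["lncRNA"], row["partner"])
                for _, row in table[table["candidate"]].iterrows()}
        truth_set = {(l, c) for l, c, _ in truth.cis_pairs}
        assert len(hits & truth_set) / len(truth_set) > 0.9

    def test_null_pairs_produce_no_candidates(self):
        # independent lncRNA/partner profiles: expect 0 calls at p < 1e-7
        cfg = CohortSimConfig(n_genes=1000, n_samples=64, module_sizes=[],
                              lncrna_fraction=0.0, tf_fraction=0.0, seed=8)
        expr, annot, _ = simulate_islet_cohort(cfg)
        annot = annot.copy()
        annot.loc[annot.index[::2], "biotype"] = "lncRNA"  # alternate labels
        table = cis_pair_scan(expr, annot)
        assert len(table) == 500
        assert table["candidate"].sum() == 0

    def test_lncrna_without_partner_excluded(self):
        annot = _annot([("chr1", 0, 100, "+", "lnc1", "lncRNA"),
                        ("chr9", 0, 100, "+", "pc1", "coding")])
        expr = pd.DataFrame(np.random.default_rng(0).normal(size=(2, 10)),
                            index=["lnc1", "pc1"])
        assert cis_pair_scan(expr, annot).empty


class TestSizeFactors:
    def test_hand_computed_median_of_ratios(self):
        counts = pd.DataFrame([[2, 4], [3, 6]], columns=["s1", "s2"])
        sf = size_factors(counts)
        assert sf["s1"] == pytest.approx(1 / np.sqrt(2), abs=1e-4)
        assert sf["s2"] == pytest.approx(np.sqrt(2), abs=1e-4)

    def test_identical_columns_equal_factors(self):
        counts = pd.DataFrame([[5, 5, 5], [9, 9, 9]])
        assert size_factors(counts).nunique() == 1

    def test_gene_order_invariance_and_column_scaling(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(50, size=(100, 4)) + 1)
        sf = size_factors(counts)
        shuffled = counts.sample(frac=1, random_state=1)
        assert np.allclose(size_factors(shuffled), sf)
        scaled = counts.copy()
        scaled[0] = scaled[0] * 3
        sf_scaled = size_factors(scaled)
        # size factors are defined relative to the geometric-mean reference,
        # so tripling one library triples its factor relative to the others
        assert sf_scaled[0] / sf_scaled[1] == pytest.approx(3 * sf[0] / sf[1])

    def test_planted_depths_recovered(self):
        cfg = CountSimConfig(n_genes=3000, n_control=3, n_case=3,
                             depth_factors=[1.0, 2.0, 4.0, 1.0, 2.0, 4.0], seed=1)
        counts, _, truth = simulate_count_cohort(cfg)
        sf = size_factors(counts)
        ratio = (sf / sf.iloc[0]).to_numpy()
        true_ratio = (truth.size_factors / truth.size_factors.iloc[0]).to_numpy()
        assert np.allclose(ratio, true_ratio, rtol=0.05)

    def test_no_universally_expressed_gene(self):
        counts = pd.DataFrame([[0, 5], [5, 0]])
        with pytest.raises(ValueError):
            size_factors(counts)


class TestNbWaldDE:
    def test_null_bh_fraction_controlled(self):
        cfg = CountSimConfig(n_genes=3000, n_control=50, n_case=15, seed=2)
        counts, conditions, _ = simulate_count_cohort(cfg)
        table = nb_wald_de(counts, conditions)
        assert table["significant"].fillna(False).mean() <= 0.05 + 0.01

    def test_power_on_planted_effects(self):
        de = {g: 2.0 if g % 2 else -2.0 for g in range(0, 200)}
        cfg = CountSimConfig(n_genes=2000, n_control=50, n_case=15,
                             de_genes=de, seed=3)
        counts, conditions, truth = simulate_count_cohort(cfg)
        table = nb_wald_de(counts, conditions)
        called = table.loc[list(truth.de_effects), "significant"].fillna(False)
        assert called.mean() > 0.8
        # effect directions recovered
        signs = np.sign(table.loc[list(truth.de_effects), "log2fc"])
        true_signs = np.sign(pd.Series(truth.de_effects))
        assert (signs == true_signs).mean() > 0.95

    def test_poisson_limit_matches_poisson_wald_oracle(self):
        rng = np.random.default_rng(4)
        mu = rng.uniform(50, 500, size=300)
        counts = pd.DataFrame(rng.poisson(np.tile(mu[:, None], (1, 20))),
                              columns=[f"s{i}" for i in range(20)])
        conditions = pd.Series(["control"] * 10 + ["case"] * 10,
                               index=counts.columns)
        sf = pd.Series(1.0, index=counts.columns)
        table = nb_wald_de(counts, conditions, sf=sf)
        # Poisson Wald oracle: Var(mean) = mean / n
        m0 = counts.iloc[:, :10].mean(axis=1)
        m1 = counts.iloc[:, 10:].mean(axis=1)
        lfc = np.log2(m1 / m0)
        se = np.sqrt((m0 / 10 / m0**2 + m1 / 10 / m1**2)) / np.log(2)
        p_oracle = 2 * stats.norm.sf(np.abs(lfc / se))
        keep = p_oracle > 1e-10
        rel = np.abs(table["p"][keep] - p_oracle[keep]) / p_oracle[keep]
        assert np.nanmedian(rel) < 0.1

    def test_all_zero_condition_gives_na(self):
        counts = pd.DataFrame({"c1": [0, 5], "c2": [0, 6], "k1": [4, 5], "k2": [5, 6]})
        conditions = pd.Series(["control", "control", "case", "case"],
                               index=counts.columns)
        table = nb_wald_de(counts, conditions, sf=pd.Series(1.0, index=counts.columns))
        assert np.isnan(table.iloc[0]["p"])
        assert not np.isnan(table.iloc[1]["p"])


class TestBhAdjust:
    def test_hand_applied_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_monotone_and_never_below_raw(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=50)
        padj = bh_adjust(p)
        assert (padj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(padj[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
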
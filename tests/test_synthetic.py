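"""Generator correctness: HWE dosages, planted LD, planted effects."""

import numpy as np
import pandas as pd
import pytest

from plasmanet import (
    SimulationConfig,
    TruthTable,
    make_truth,
    simulate_dataset,
    simulate_expression,
    simulate_genotypes,
    simulate_proteins,
    simulate_summary_pair,
)
from plasmanet.synthetic import _genotype_thresholds


def big_config(**kw) -> SimulationConfig:
    base = dict(n_samples=10_000, n_genes=2, n_tissues=1, snps_per_gene=10,
                n_modules=1, module_size=1, rng_seed=5)
    base.update(kw)
    return SimulationConfig(**base)


class TestGenotypes:
    def test_dosages_are_hwe_counts(self, small_dataset):
        geno = small_dataset[0]
        vals = np.unique(geno.dosages.to_numpy())
        assert set(vals) <= {0, 1, 2}
        assert not geno.dosages.isna().any().any()

    def test_empirical_maf_near_target(self):
        geno = simulate_genotypes(big_config())
        assert (geno.maf() >= 0.05 - 0.02).all()

    def test_fixed_maf_half_gives_mean_dosage_one(self):
        geno = simulate_genotypes(big_config(maf_low=0.5, maf_high=0.5))
        means = geno.dosages.mean(axis=0)
        assert np.allclose(means, 1.0, atol=0.05)

    def test_no_ld_gives_uncorrelated_snps(self):
        geno = simulate_genotypes(big_config(ld_rho=0.0))
        r = np.corrcoef(geno.dosages.to_numpy(float).T)
        off = np.abs(r[np.triu_indices_from(r, k=1)])
        assert off.mean() < 0.05

    def test_adjacent_ld_matches_copula_monte_carlo_oracle(self):
        """Thresholded-Gaussian copula MC at 1e6 draws is the reference
        for the adjacent-SNP dosage correlation at ld_rho = 0.9."""
        rho, p = 0.9, 0.3
        mc = np.random.default_rng(99)
        z1 = mc.standard_normal(1_000_000)
        z2 = rho * z1 + np.sqrt(1 - rho * rho) * mc.standard_normal(1_000_000)
        c0, c1 = _genotype_thresholds(np.array([p]))
        d1 = (z1 > c0[0]).astype(int) + (z1 > c1[0]).astype(int)
        d2 = (z2 > c0[0]).astype(int) + (z2 > c1[0]).astype(int)
        oracle = np.corrcoef(d1, d2)[0, 1]

        geno = simulate_genotypes(big_config(
            ld_rho=rho, ld_block_size=5, maf_low=p, maf_high=p))
        D = geno.dosages.to_numpy(float)
        rs = [np.corrcoef(D[:, j - 1], D[:, j])[0, 1]
              for j in range(1, geno.n_snps) if j % 5 != 0 and j % 10 != 0]
        assert abs(np.mean(rs) - oracle) < 0.03

    def test_ld_increases_with_rho(self):
        def mean_adj(rho):
            geno = simulate_genotypes(
                SimulationConfig(n_samples=2000, n_genes=2, n_tissues=1,
                                 snps_per_gene=10, ld_block_size=10,
                                 ld_rho=rho, rng_seed=3))
            D = geno.dosages.to_numpy(float)
            return np.mean([np.corrcoef(D[:, j - 1], D[:, j])[0, 1]
                            for j in range(1, 10)])

        assert mean_adj(0.2) < mean_adj(0.6) < mean_adj(0.95)

    def test_refuses_tiny_cohort(self):
        with pytest.raises(ValueError, match="n_samples"):
            SimulationConfig(n_samples=5)

    def test_bit_identical_regeneration(self, small_config):
        a = simulate_dataset(small_config)
        b = simulate_dataset(small_config)
        pd.testing.assert_frame_equal(a[0].dosages, b[0].dosages)
        for t in a[1]:
            pd.testing.assert_frame_equal(a[1][t], b[1][t])
        pd.testing.assert_frame_equal(a[2], b[2])
        assert a[3].eqtl_beta == b[3].eqtl_beta


class TestExpression:
    def test_null_eqtl_leaves_no_dosage_signal(self):
        cfg = big_config(n_genes=20)
        geno = simulate_genotypes(cfg)
        truth = make_truth(cfg)
        truth.eqtl_beta = {k: 0.0 for k in truth.eqtl_beta}
        truth.module_membership = {}
        expr = simulate_expression(geno, truth, cfg)["T1"]
        n = cfg.n_samples
        cors = [abs(np.corrcoef(
            expr[g], geno.dosages[truth.causal_snp_per_gene[g]])[0, 1])
            for g in cfg.gene_ids]
        assert np.quantile(cors, 0.95) < 2.58 / np.sqrt(n)

    def test_unit_effect_r2_matches_hwe_closed_form(self):
        """beta=1, sigma=1, maf=0.5: R^2 = 2p(1-p)/(2p(1-p)+1) = 1/3."""
        cfg = big_config(maf_low=0.5, maf_high=0.5, eqtl_effect_sd=1.0)
        geno = simulate_genotypes(cfg)
        truth = make_truth(cfg)
        truth.eqtl_beta = {k: 1.0 for k in truth.eqtl_beta}
        truth.module_membership = {}
        expr = simulate_expression(geno, truth, cfg)["T1"]
        g = cfg.gene_ids[0]
        r = np.corrcoef(expr[g], geno.dosages[truth.causal_snp_per_gene[g]])[0, 1]
        assert abs(r * r - 1.0 / 3.0) < 0.03

    def test_shared_module_factor_dominates(self):
        cfg = SimulationConfig(n_samples=500, n_genes=2, n_tissues=1,
                               snps_per_gene=2, n_modules=1, module_size=2,
                               module_loading=10.0, rng_seed=9)
        geno = simulate_genotypes(cfg)
        truth = make_truth(cfg)
        truth.eqtl_beta = {k: 0.0 for k in truth.eqtl_beta}
        truth.module_membership = {("G0001", "T1"): "M001",
                                   ("G0002", "T1"): "M001"}
        expr = simulate_expression(geno, truth, cfg)["T1"]
        assert np.corrcoef(expr["G0001"], expr["G0002"])[0, 1] > 0.9

    def test_planted_beta_recovered_by_ols(self):
        """Planted eQTL effect within 3 SE of the OLS estimate in >= 95%
        of replicates (simple regression on the causal dosage)."""
        hits = 0
        reps = 200
        for seed in range(reps):
            cfg = SimulationConfig(n_samples=200, n_genes=1, n_tissues=1,
                                   snps_per_gene=2, rng_seed=seed)
            geno = simulate_genotypes(cfg)
            truth = make_truth(cfg)
            truth.module_membership = {}
            beta_true = truth.eqtl_beta[("G0001", "T1")]
            expr = simulate_expression(geno, truth, cfg)["T1"]
            x = geno.dosages[truth.causal_snp_per_gene["G0001"]].to_numpy(float)
            y = expr["G0001"].to_numpy(float)
            xc = x - x.mean()
            b = xc @ (y - y.mean()) / (xc @ xc)
            resid = y - y.mean() - b * xc
            se = np.sqrt(resid @ resid / (len(y) - 2) / (xc @ xc))
            hits += abs(b - beta_true) <= 3 * se
        assert hits >= 0.95 * reps


class TestProteins:
    def test_noise_free_single_tissue_transmission_is_identity(self):
        from scipy import stats

        cfg = SimulationConfig(n_samples=300, n_genes=1, n_tissues=2,
                               snps_per_gene=2, protein_noise_sd=1e-8,
                               rng_seed=2)
        geno = simulate_genotypes(cfg)
        truth = make_truth(cfg)
        truth.module_membership = {}
        truth.protein_module_effects = {}
        truth.seed_weights = {("P0001", "T1"): 1.0}
        expr = simulate_expression(geno, truth, cfg)
        prot = simulate_proteins(expr, geno, truth, cfg)
        rho = stats.spearmanr(prot["P0001"], expr["T1"]["G0001"]).statistic
        assert rho > 0.99

    def test_zero_effects_give_null_correlations(self):
        cfg = SimulationConfig(n_samples=1000, n_genes=10, n_tissues=1,
                               snps_per_gene=2, rng_seed=3)
        geno = simulate_genotypes(cfg)
        truth = make_truth(cfg)
        truth.seed_weights = {}
        truth.protein_module_effects = {}
        expr = simulate_expression(geno, truth, cfg)
        prot = simulate_proteins(expr, geno, truth, cfg)
        assert set(truth.pure_noise_proteins) == set(cfg.protein_ids)
        cors = np.abs(np.corrcoef(
            prot.to_numpy(float).T, expr["T1"].to_numpy(float).T
        )[:10, 10:])
        assert cors.max() < 4.5 / np.sqrt(cfg.n_samples)

    def test_planted_genetic_variance_fraction_realized(self):
        """R^2 of protein on causal dosage hits the 0.2 target at n=10,000."""
        cfg = big_config(n_genes=3)
        geno = simulate_genotypes(cfg)
        truth = make_truth(cfg)
        truth.protein_genetic_variance_fraction = {
            p: 0.2 for p in cfg.protein_ids}
        expr = simulate_expression(geno, truth, cfg)
        prot = simulate_proteins(expr, geno, truth, cfg)
        for p_id, g in zip(cfg.protein_ids, cfg.gene_ids):
            x = geno.dosages[truth.causal_snp_per_gene[g]].to_numpy(float)
            r = np.corrcoef(prot[p_id], x)[0, 1]
            assert abs(r * r - 0.2) < 0.03
            assert abs(truth.realized_genetic_variance_fraction[p_id]
                       - r * r) < 1e-12

    def test_realized_fraction_tracks_target_on_average(self):
        """Mean realized fraction within 0.03 of the target over replicates."""
        realized = []
        for seed in range(20):
            cfg = SimulationConfig(n_samples=10_000, n_genes=1, n_tissues=1,
                                   snps_per_gene=2, rng_seed=seed)
            geno = simulate_genotypes(cfg)
            truth = make_truth(cfg)
            truth.protein_genetic_variance_fraction = {"P0001": 0.2}
            expr = simulate_expression(geno, truth, cfg)
            prot = simulate_proteins(expr, geno, truth, cfg)
            realized.append(truth.realized_genetic_variance_fraction["P0001"])
        assert abs(np.mean(realized) - 0.2) < 0.03


class TestSummaryPairs:
    def test_null_scenario_small_z(self):
        s1, s2 = simulate_summary_pair("null", 50, 5000, 5000, rng_seed=1)
        for s in (s1, s2):
            z = s.table["beta"] / np.sqrt(s.table["varbeta"])
            assert np.abs(z).max() < 5

    def test_shared_scenario_same_top_snp(self):
        s1, s2 = simulate_summary_pair("shared", 50, 5000, 5000, 8.0, 1)
        z1 = (s1.table["beta"] / np.sqrt(s1.table["varbeta"])).abs()
        z2 = (s2.table["beta"] / np.sqrt(s2.table["varbeta"])).abs()
        assert z1.idxmax() == z2.idxmax() == 25

    def test_distinct_scenario_different_top_snps(self):
        s1, s2 = simulate_summary_pair("distinct", 50, 5000, 5000, 8.0, 1)
        z1 = (s1.table["beta"] / np.sqrt(s1.table["varbeta"])).abs()
        z2 = (s2.table["beta"] / np.sqrt(s2.table["varbeta"])).abs()
        assert z1.idxmax() != z2.idxmax()

    def test_distinct_needs_two_snps(self):
        with pytest.raises(ValueError, match="region_size"):
            simulate_summary_pair("distinct", 1, 100, 100)

    def test_invariants_of_truth_table(self):
        with pytest.raises(ValueError, match="variance fractions"):
            TruthTable(causal_snp_per_gene={}, eqtl_beta={}, seed_weights={},
                       module_membership={}, protein_module_effects={},
                       protein_genetic_variance_fraction={"P1": 1.5})
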
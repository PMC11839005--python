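"""Spearman, Storey q-values, QQ tables, multivariate cross-tissue model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from plasmanet import (
    SimulationConfig,
    correlate_seed_genes,
    multivariate_seed_model,
    multivariate_seed_table,
    qq_compare,
    qvalues,
    simulate_dataset,
    spearman,
    spearman_grid,
)
from plasmanet.seed import estimate_pi0
from plasmanet.synthetic import make_truth, protein_gene_map


class TestSpearman:
    def test_monotone_transform_gives_unit_rho(self, rng):
        x = rng.normal(size=30)
        rho, _ = spearman(x, x ** 3)
        assert rho == pytest.approx(1.0)
        rho, _ = spearman(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_sum_d_squared_oracle(self):
        """rho = 1 - 6*sum(d^2)/(n(n^2-1)) for untied ranks."""
        x = np.array([1, 2, 3, 4, 5], float)
        y = np.array([2, 1, 4, 3, 5], float)
        d2 = ((stats.rankdata(x) - stats.rankdata(y)) ** 2).sum()
        oracle = 1 - 6 * d2 / (5 * 24)
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_invariant_under_random_monotone_transforms(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        base, _ = spearman(x, y)
        for _ in range(20):
            a, b = rng.uniform(0.1, 3.0, size=2)
            fx = np.exp(a * x)          # strictly increasing
            fy = np.sign(y) * np.abs(y) ** b if rng.random() < 0.5 else b * y
            rho, _ = spearman(fx, fy)
            assert rho == pytest.approx(base, abs=1e-12)

    def test_exact_permutation_p(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([1.0, 2.0, 3.0, 5.0, 4.0])
        rho, p = spearman(x, y, exact=True)
        # count pairings with |rho| >= observed by full enumeration
        from itertools import permutations
        rx = stats.rankdata(x)
        count = 0
        for perm in permutations(range(5)):
            r = np.corrcoef(rx[list(perm)], stats.rankdata(y))[0, 1]
            count += abs(r) >= abs(rho) - 1e-12
        assert p == pytest.approx(count / 120)

    def test_constant_vector_undefined(self):
        with pytest.raises(ValueError, match="constant"):
            spearman(np.ones(10), np.arange(10.0))

    def test_grid_matches_scipy_pairwise(self, rng):
        left = pd.DataFrame(rng.normal(size=(50, 4)))
        right = pd.DataFrame(rng.normal(size=(50, 3)))
        rho, p = spearman_grid(left, right)
        for i in range(4):
            for j in range(3):
                ref = stats.spearmanr(left.iloc[:, i], right.iloc[:, j])
                assert rho.iloc[i, j] == pytest.approx(ref.statistic,
                                                       abs=1e-12)
                assert p.iloc[i, j] == pytest.approx(ref.pvalue, rel=1e-9)


class TestQvalues:
    def test_all_ones(self):
        q = qvalues(np.ones(200))
        assert (q == 1.0).all()

    def test_pi0_near_one_under_uniform(self, rng):
        """pi0-hat within the clip bounds [0.9, 1] for most replicates."""
        ok = 0
        for _ in range(30):
            pi0 = estimate_pi0(rng.uniform(size=10_000))
            ok += 0.9 <= pi0 <= 1.0
        assert ok >= 27

    def test_pi0_recovers_spiked_mixture(self, rng):
        """30% near-zero p-values: pi0-hat ~ 0.7."""
        vals = []
        for _ in range(20):
            p = np.concatenate([rng.uniform(size=7000),
                                rng.uniform(0, 1e-4, size=3000)])
            vals.append(estimate_pi0(p))
        assert abs(np.mean(vals) - 0.7) < 0.07

    def test_monotone_in_p(self, rng):
        p = rng.uniform(size=500)
        q = qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_q_at_least_bh_when_pi0_one(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=50)  # m < 100 -> pi0 = 1 fallback
        q = qvalues(p)
        _, bh, *_ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, bh, atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            qvalues(np.array([0.5, 1.5]))


class TestQQCompare:
    def test_uniform_slope_near_one(self, rng):
        tab = qq_compare(rng.uniform(size=10_000), rng.uniform(size=10_000))
        a = tab[tab["group"] == "a"]
        slope = np.polyfit(a["expected"], a["observed"], 1)[0]
        assert 0.9 <= slope <= 1.1

    def test_enriched_vector_dominates_at_tail(self, rng):
        null = rng.uniform(size=2000)
        enriched = np.concatenate([rng.uniform(size=1500),
                                   rng.uniform(0, 1e-3, size=500)])
        tab = qq_compare(null, enriched, labels=("null", "enriched"))
        tail = tab[tab["expected"] > 2]
        null_tail = tail[tail["group"] == "null"]["observed"].mean()
        enr_tail = tail[tail["group"] == "enriched"]["observed"].mean()
        assert enr_tail > null_tail

    def test_identical_vectors_identical_curves(self, rng):
        p = rng.uniform(size=100)
        tab = qq_compare(p, p.copy())
        a = tab[tab["group"] == "a"].reset_index(drop=True)
        b = tab[tab["group"] == "b"].reset_index(drop=True)
        assert np.allclose(a["observed"], b["observed"])


class TestCorrelateSeedGenes:
    def test_planted_transmission_flagged_in_planted_tissue(self):
        cfg = SimulationConfig(n_samples=300, n_genes=120, n_tissues=2,
                               snps_per_gene=2, protein_noise_sd=0.05,
                               rng_seed=4)
        truth = make_truth(cfg)
        truth.module_membership = {}
        truth.protein_module_effects = {}
        truth.seed_weights = {(p, "T1"): 1.0 for p in cfg.protein_ids}
        _, expr, prot, truth, _ = simulate_dataset(cfg, truth=truth)
        rec = correlate_seed_genes(expr, prot, protein_gene_map(cfg))
        t1 = rec[rec["tissue"] == "T1"]
        assert t1["significant"].mean() > 0.95

    def test_null_transmission_false_positive_rate(self):
        cfg = SimulationConfig(n_samples=300, n_genes=150, n_tissues=2,
                               snps_per_gene=2, rng_seed=5)
        truth = make_truth(cfg)
        truth.module_membership = {}
        truth.protein_module_effects = {}
        truth.seed_weights = {}
        _, expr, prot, truth, _ = simulate_dataset(cfg, truth=truth)
        rec = correlate_seed_genes(expr, prot, protein_gene_map(cfg))
        assert rec["significant"].mean() <= 0.05 + 0.03

    def test_single_tissue_transmission_recovery(self):
        """Liver-style design: transmission only in tissue T1 for all
        proteins; nearly all recovered as T1 seed genes at q <= 0.05."""
        cfg = SimulationConfig(n_samples=500, n_genes=50, n_tissues=7,
                               snps_per_gene=2, rng_seed=6)
        truth = make_truth(cfg)
        truth.module_membership = {}
        truth.protein_module_effects = {}
        truth.seed_weights = {(p, "T1"): 1.0 for p in cfg.protein_ids}
        _, expr, prot, truth, _ = simulate_dataset(cfg, truth=truth)
        rec = correlate_seed_genes(expr, prot, protein_gene_map(cfg))
        hits = rec[(rec["tissue"] == "T1") & rec["significant"]]
        assert len(hits) >= 45

    def test_per_tissue_scope_available(self, small_dataset, small_config,
                                        small_p2g):
        _, expr, prot = small_dataset[:3]
        rec = correlate_seed_genes(expr, prot, small_p2g,
                                   fdr_scope="per_tissue")
        assert set(rec["tissue"]) <= set(small_config.tissues)


class TestMultivariateModel:
    def test_matches_pseudoinverse_oracle(self, rng):
        idx = pd.Index([f"S{i}" for i in range(60)])
        X = {t: pd.Series(rng.normal(size=60), index=idx)
             for t in ["T1", "T2", "T3"]}
        y = pd.Series(rng.normal(size=60), index=idx, name="P1")
        fit = multivariate_seed_model(y, X)
        D = np.column_stack([np.ones(60)] + [X[t].to_numpy()
                                             for t in ["T1", "T2", "T3"]])
        oracle = np.linalg.pinv(D) @ y.to_numpy()
        assert abs(fit.intercept - oracle[0]) < 1e-10
        assert np.abs(fit.coefficients["beta"].to_numpy()
                      - oracle[1:]).max() < 1e-10

    def test_single_tissue_reduces_to_simple_regression(self, rng):
        idx = pd.Index([f"S{i}" for i in range(50)])
        x = pd.Series(rng.normal(size=50), index=idx)
        y = pd.Series(2.0 * x + rng.normal(size=50), index=idx, name="P1")
        fit = multivariate_seed_model(y, {"T1": x})
        xc = x - x.mean()
        beta_simple = float(xc @ (y - y.mean()) / (xc @ xc))
        assert fit.coefficients.loc["T1", "beta"] == pytest.approx(
            beta_simple, abs=1e-12)

    def test_orthogonal_weights_recovered(self, rng):
        idx = pd.Index([f"S{i}" for i in range(400)])
        x1 = pd.Series(rng.normal(size=400), index=idx)
        x2 = pd.Series(rng.normal(size=400), index=idx)
        y = pd.Series(1.0 * x1 + 0.5 * x2 + rng.normal(size=400),
                      index=idx, name="P1")
        fit = multivariate_seed_model(y, {"T1": x1, "T2": x2})
        for t, w in [("T1", 1.0), ("T2", 0.5)]:
            row = fit.coefficients.loc[t]
            assert abs(row["beta"] - w) <= 3 * row["se"]

    def test_collinear_tissue_dropped(self, rng):
        idx = pd.Index([f"S{i}" for i in range(50)])
        x = pd.Series(rng.normal(size=50), index=idx)
        y = pd.Series(x + rng.normal(size=50), index=idx, name="P1")
        fit = multivariate_seed_model(y, {"T1": x, "T2": 2.0 * x})
        assert len(fit.coefficients) == 1

    def test_marginal_association_lost_after_adjustment(self):
        """Cross-tissue confounding: a tissue correlated with the true
        transmitting tissue is marginally associated but loses
        significance in the joint model for most planted cases."""
        rng = np.random.default_rng(11)
        lost = 0
        reps = 20
        for _ in range(reps):
            n = 200
            idx = pd.Index([f"S{i}" for i in range(n)])
            driver = rng.normal(size=n)
            proxy = driver + 0.5 * rng.normal(size=n)  # correlated tissue
            y = pd.Series(driver + 0.7 * rng.normal(size=n), index=idx,
                          name="P1")
            x1 = pd.Series(driver, index=idx)
            x2 = pd.Series(proxy, index=idx)
            marg_p = stats.spearmanr(x2, y).pvalue
            fit = multivariate_seed_model(y, {"T1": x1, "T2": x2})
            joint_p = fit.coefficients.loc["T2", "p"]
            if marg_p < 0.05 and joint_p > 0.05:
                lost += 1
        assert lost >= 0.8 * reps

    def test_table_excludes_unexpressed_and_pools_family(self):
        cfg = SimulationConfig(n_samples=150, n_genes=10, n_tissues=2,
                               snps_per_gene=2, rng_seed=8)
        _, expr, prot, truth, _ = simulate_dataset(cfg)
        p2g = protein_gene_map(cfg)
        p2g["PX"] = "G_ABSENT"
        tab = multivariate_seed_table(expr, prot, p2g)
        assert "PX" not in set(tab["protein_id"])
        assert len(tab) == 10 * 2
        assert "q" in tab.columns
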
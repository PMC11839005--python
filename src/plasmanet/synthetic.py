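"""Synthetic multi-tissue genotype / expression / protein generator.

The generator plants a fully known causal structure — which SNP drives which
gene in which tissue, which tissues transmit a seed gene into its plasma
protein, and which co-expression module feeds which protein — so that every
downstream stage (QTL mapping, coherence calls, colocalization, seed-gene
and eigengene association) can be validated against ground truth without
access-restricted human data.

Model
-----
* Genotypes: Hardy–Weinberg dosages in {0,1,2} obtained by thresholding a
  latent standard Gaussian at the cumulative genotype frequencies
  ``(1-p)^2`` and ``(1-p)^2 + 2p(1-p)``; linkage disequilibrium is induced
  by AR(1) correlation ``ld_rho`` between latent variables inside blocks of
  ``ld_block_size`` adjacent SNPs. Blocks never straddle genes.
* Expression of gene g in tissue t:
  ``beta(g,t) * dosage(causal SNP of g) + loading * F_m + N(0, noise_sd)``
  where ``F_m`` is the standard-normal latent factor of the module the
  (gene, tissue) pair belongs to, if any.
* Plasma protein p (one per gene, its "seed" gene):
  ``sum_t w(p,t) * expr(seed gene, t) + gamma_p * dosage(causal SNP)
  + sum_m e(p,m) * F_m + N(0, noise_sd)``.
  When a target cis-genetic variance fraction is planted for p, the direct
  effect ``gamma_p`` is solved so the total regression R^2 of the protein
  on its causal dosage equals that fraction; the realized fraction is
  recorded back into the truth table.

Every draw flows from a single ``numpy.random.default_rng(rng_seed)``, so a
fixed config reproduces outputs bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from plasmanet.core import FeatureMatrix, GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "make_truth",
    "make_category_design",
    "gene_annotation",
    "protein_gene_map",
    "membership_table",
    "simulate_genotypes",
    "simulate_expression",
    "simulate_proteins",
    "simulate_summary_pair",
    "simulate_dataset",
    "write_dataset",
]

#: genomic spacing between simulated gene loci (bp); adjacent ±500 kb cis
#: windows touch but never overlap at this spacing
GENE_SPACING = 1_000_000
SNP_SPACING = 2_000


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror a mid-sized multi-tissue proteogenomic cohort: ~500
    genotyped individuals, seven tissues, dense local SNP coverage around
    each gene, and co-expression modules spanning one or several tissues.
    """

    n_samples: int = 500
    n_genes: int = 200
    n_tissues: int = 7
    snps_per_gene: int = 50
    maf_low: float = 0.05
    maf_high: float = 0.5
    ld_block_size: int = 10
    ld_rho: float = 0.8
    eqtl_effect_sd: float = 0.5
    seed_weight_range: tuple[float, float] = (0.3, 1.0)
    n_modules: int = 20
    module_size: int = 10
    eigengene_effect_sd: float = 0.5
    module_loading: float = 1.0
    noise_sd: float = 1.0
    protein_noise_sd: Optional[float] = None  # defaults to noise_sd
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_genes", "n_tissues", "snps_per_gene",
                     "ld_block_size", "n_modules", "module_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_samples < 10:
            raise ValueError("n_samples < 10: downstream regressions unreliable")
        if not 0.05 <= self.maf_low <= self.maf_high <= 0.5:
            raise ValueError("need 0.05 <= maf_low <= maf_high <= 0.5")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError("ld_rho must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.protein_noise_sd is not None and self.protein_noise_sd <= 0:
            raise ValueError("protein_noise_sd must be positive")

    @property
    def n_snps(self) -> int:
        return self.n_genes * self.snps_per_gene

    @property
    def tissues(self) -> list[str]:
        return [f"T{i + 1}" for i in range(self.n_tissues)]

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i + 1:04d}" for i in range(self.n_genes)]

    @property
    def protein_ids(self) -> list[str]:
        return [f"P{i + 1:04d}" for i in range(self.n_genes)]

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i + 1:04d}" for i in range(self.n_samples)]

    @property
    def snp_ids(self) -> list[str]:
        return [f"rs{i + 1:06d}" for i in range(self.n_snps)]


@dataclass
class TruthTable:
    """Planted causal structure of one simulated dataset.

    All maps use string identifiers matching the generated matrices.
    ``protein_genetic_variance_fraction`` holds the *target* fractions
    passed in; ``realized_genetic_variance_fraction`` is filled in by
    :func:`simulate_proteins` with the empirical regression R^2 actually
    achieved in the generated cohort.
    """

    causal_snp_per_gene: dict[str, str]
    eqtl_beta: dict[tuple[str, str], float]
    seed_weights: dict[tuple[str, str], float]
    module_membership: dict[tuple[str, str], str]
    protein_module_effects: dict[tuple[str, str], float]
    protein_genetic_variance_fraction: dict[str, float] = field(default_factory=dict)
    realized_genetic_variance_fraction: dict[str, float] = field(default_factory=dict)
    pure_noise_proteins: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for frac in self.protein_genetic_variance_fraction.values():
            if not 0.0 <= frac < 1.0:
                raise ValueError("target variance fractions must lie in [0, 1)")

    def module_ids(self) -> list[str]:
        return sorted(set(self.module_membership.values()))

    def members_of(self, module_id: str) -> list[tuple[str, str]]:
        return [k for k, m in self.module_membership.items() if m == module_id]

    def to_json(self) -> str:
        def enc(d):
            return {("|".join(k) if isinstance(k, tuple) else k): v
                    for k, v in d.items()}

        payload = {
            "causal_snp_per_gene": self.causal_snp_per_gene,
            "eqtl_beta": enc(self.eqtl_beta),
            "seed_weights": enc(self.seed_weights),
            "module_membership": enc(self.module_membership),
            "protein_module_effects": enc(self.protein_module_effects),
            "protein_genetic_variance_fraction": self.protein_genetic_variance_fraction,
            "realized_genetic_variance_fraction": self.realized_genetic_variance_fraction,
            "pure_noise_proteins": self.pure_noise_proteins,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def _genotype_thresholds(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Latent-Gaussian cut points for HWE genotype frequencies at allele
    frequency p (dosage counts copies of the frequency-p allele)."""
    q = 1.0 - p
    c0 = stats.norm.ppf(q * q)
    c1 = stats.norm.ppf(q * q + 2.0 * p * q)
    return c0, c1


def simulate_genotypes(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> GenotypeMatrix:
    """Draw HWE dosages with block-AR(1) LD via a thresholded Gaussian copula.

    SNP ``j`` of gene ``g`` sits at position ``g*GENE_SPACING + 500_000 -
    (snps_per_gene//2 - j)*SNP_SPACING`` so every SNP lies well inside its
    gene's ±500 kb cis window and outside every other gene's window.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    n, m = config.n_samples, config.n_snps
    spg = config.snps_per_gene

    # latent AR(1) within blocks; blocks restart at gene boundaries
    z = np.empty((n, m))
    innov = rng.standard_normal((n, m))
    rho = config.ld_rho
    scale = np.sqrt(1.0 - rho * rho)
    for j in range(m):
        new_block = (j % config.ld_block_size == 0) or (j % spg == 0)
        if new_block:
            z[:, j] = innov[:, j]
        else:
            z[:, j] = rho * z[:, j - 1] + scale * innov[:, j]

    p = rng.uniform(config.maf_low, config.maf_high, size=m)
    c0, c1 = _genotype_thresholds(p)
    dosages = (z > c0).astype(np.int8) + (z > c1).astype(np.int8)

    gene_idx = np.arange(m) // spg
    within = np.arange(m) % spg
    pos = gene_idx * GENE_SPACING + 500_000 + (within - spg // 2) * SNP_SPACING
    snp_info = pd.DataFrame(
        {"chrom": "1", "pos": pos.astype(np.int64), "freq": p},
        index=pd.Index(config.snp_ids, name="snp_id"),
    )
    dos = pd.DataFrame(
        dosages, index=pd.Index(config.sample_ids, name="sample_id"),
        columns=snp_info.index,
    )
    return GenotypeMatrix(dosages=dos, snp_info=snp_info)


def make_truth(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    genetic_variance_fraction: Optional[dict[str, float]] = None,
) -> TruthTable:
    """Draw a default truth table for ``config``.

    * the causal SNP of each gene is the central SNP of its local run;
    * per-(gene, tissue) eQTL effects are N(0, eqtl_effect_sd^2);
    * each protein receives seed-gene transmission from one random tissue
      with weight uniform in ``seed_weight_range``, and one random module
      effect N(0, eigengene_effect_sd^2);
    * half the modules are tissue-specific (all members one tissue), half
      cross-tissue (members spread over tissues).
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed + 1)
    genes, tissues = config.gene_ids, config.tissues
    proteins = config.protein_ids
    spg = config.snps_per_gene

    causal = {g: config.snp_ids[i * spg + spg // 2] for i, g in enumerate(genes)}
    eqtl_beta = {
        (g, t): float(rng.normal(0.0, config.eqtl_effect_sd))
        for g in genes for t in tissues
    }

    lo, hi = config.seed_weight_range
    seed_weights: dict[tuple[str, str], float] = {}
    for p_id in proteins:
        t = tissues[rng.integers(len(tissues))]
        seed_weights[(p_id, t)] = float(rng.uniform(lo, hi))

    membership: dict[tuple[str, str], str] = {}
    for mi in range(config.n_modules):
        mod = f"M{mi + 1:03d}"
        member_genes = rng.choice(len(genes), size=min(config.module_size, len(genes)),
                                  replace=False)
        if mi < config.n_modules // 2:  # tissue-specific
            t = tissues[int(rng.integers(len(tissues)))]
            for gi in member_genes:
                membership[(genes[gi], t)] = mod
        else:  # cross-tissue
            for gi in member_genes:
                t = tissues[int(rng.integers(len(tissues)))]
                membership[(genes[gi], t)] = mod

    module_ids = sorted(set(membership.values()))
    module_effects: dict[tuple[str, str], float] = {}
    for p_id in proteins:
        mod = module_ids[int(rng.integers(len(module_ids)))]
        module_effects[(p_id, mod)] = float(rng.normal(0.0, config.eigengene_effect_sd))

    return TruthTable(
        causal_snp_per_gene=causal,
        eqtl_beta=eqtl_beta,
        seed_weights=seed_weights,
        module_membership=membership,
        protein_module_effects=module_effects,
        protein_genetic_variance_fraction=dict(genetic_variance_fraction or {}),
    )


def gene_annotation(config: SimulationConfig) -> pd.DataFrame:
    """TSS annotation implied by the generator's genomic layout."""
    tss = np.arange(config.n_genes) * GENE_SPACING + 500_000
    return pd.DataFrame(
        {"chrom": "1", "tss": tss.astype(np.int64)},
        index=pd.Index(config.gene_ids, name="gene_id"))


def protein_gene_map(config: SimulationConfig) -> dict[str, str]:
    """Protein -> coding ("seed") gene map; one protein per gene."""
    return dict(zip(config.protein_ids, config.gene_ids))


def membership_table(truth: TruthTable) -> pd.DataFrame:
    """Module membership in the on-disk TSV layout (module_id, gene_id, tissue)."""
    rows = [(m, g, t) for (g, t), m in truth.module_membership.items()]
    return pd.DataFrame(rows, columns=["module_id", "gene_id", "tissue"])


def make_category_design(
    config: SimulationConfig,
    n_per_class: int = 30,
    seed_weight: float = 1.0,
    module_effect: float = 1.0,
    rng: Optional[np.random.Generator] = None,
) -> tuple[TruthTable, dict[str, str]]:
    """Truth table with three planted protein classes for recovery tests.

    The first ``n_per_class`` proteins are driven purely by seed-gene
    transmission (weight ``seed_weight`` from one tissue), the next block
    purely by one tissue-specific module eigengene, the last block purely
    by one cross-tissue module eigengene (effect ``module_effect``).
    Module member genes are drawn from outside the designed protein
    blocks so the three mechanisms stay separable. Returns (truth,
    expected category per protein id).

    Requires n_genes >= 3*n_per_class + module member pool and
    n_modules >= 2 (half tissue-specific, half cross-tissue).
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed + 7)
    n_designed = 3 * n_per_class
    if config.n_genes <= n_designed:
        raise ValueError("n_genes must exceed 3 * n_per_class")
    if config.n_modules < 2:
        raise ValueError("need at least 2 modules")

    genes, tissues, proteins = config.gene_ids, config.tissues, config.protein_ids
    spg = config.snps_per_gene
    causal = {g: config.snp_ids[i * spg + spg // 2] for i, g in enumerate(genes)}
    eqtl_beta = {(g, t): float(rng.normal(0.0, config.eqtl_effect_sd))
                 for g in genes for t in tissues}

    # modules live on the gene pool beyond the designed blocks
    pool = list(range(n_designed, config.n_genes))
    n_ts = config.n_modules // 2
    membership: dict[tuple[str, str], str] = {}
    ts_modules, ct_modules = [], []
    for mi in range(config.n_modules):
        mod = f"M{mi + 1:03d}"
        size = min(config.module_size, len(pool))
        member_genes = rng.choice(pool, size=size, replace=False)
        if mi < n_ts:
            t = tissues[int(rng.integers(len(tissues)))]
            pairs = [(genes[gi], t) for gi in member_genes]
            ts_modules.append(mod)
        else:
            ts = rng.integers(len(tissues), size=size)
            pairs = [(genes[gi], tissues[int(ti)])
                     for gi, ti in zip(member_genes, ts)]
            ct_modules.append(mod)
        for key in pairs:
            if key not in membership:  # keep (gene, tissue) in one module
                membership[key] = mod

    seed_weights: dict[tuple[str, str], float] = {}
    module_effects: dict[tuple[str, str], float] = {}
    expected: dict[str, str] = {}
    for i in range(n_per_class):
        p_id = proteins[i]
        t = tissues[int(rng.integers(len(tissues)))]
        seed_weights[(p_id, t)] = seed_weight
        expected[p_id] = "seed_gene"
    for i in range(n_per_class, 2 * n_per_class):
        p_id = proteins[i]
        mod = ts_modules[int(rng.integers(len(ts_modules)))]
        module_effects[(p_id, mod)] = module_effect
        expected[p_id] = "tissue_specific_grn"
    for i in range(2 * n_per_class, 3 * n_per_class):
        p_id = proteins[i]
        mod = ct_modules[int(rng.integers(len(ct_modules)))]
        module_effects[(p_id, mod)] = module_effect
        expected[p_id] = "cross_tissue_grn"

    truth = TruthTable(
        causal_snp_per_gene=causal,
        eqtl_beta=eqtl_beta,
        seed_weights=seed_weights,
        module_membership=membership,
        protein_module_effects=module_effects,
    )
    return truth, expected


def _module_factors(
    truth: TruthTable, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    mods = truth.module_ids()
    vals = rng.standard_normal((config.n_samples, len(mods)))
    return pd.DataFrame(vals, index=pd.Index(config.sample_ids, name="sample_id"),
                        columns=mods)


def simulate_expression(
    genotypes: GenotypeMatrix,
    truth: TruthTable,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    module_factors: Optional[pd.DataFrame] = None,
) -> dict[str, FeatureMatrix]:
    """Per-tissue expression: planted cis effect + module factor + noise."""
    if rng is None:
        rng = np.random.default_rng(config.rng_seed + 2)
    if module_factors is None:
        module_factors = _module_factors(truth, config, rng)

    genes = config.gene_ids
    out: dict[str, FeatureMatrix] = {}
    for t in config.tissues:
        mat = rng.normal(0.0, config.noise_sd,
                         size=(config.n_samples, len(genes)))
        for gi, g in enumerate(genes):
            beta = truth.eqtl_beta.get((g, t), 0.0)
            if beta != 0.0:
                snp = truth.causal_snp_per_gene[g]
                mat[:, gi] += beta * genotypes.dosages[snp].to_numpy(float)
            mod = truth.module_membership.get((g, t))
            if mod is not None:
                mat[:, gi] += config.module_loading * module_factors[mod].to_numpy()
        out[t] = pd.DataFrame(
            mat, index=genotypes.sample_ids, columns=pd.Index(genes, name="gene_id")
        )
    return out


def _univariate_r2(y: np.ndarray, x: np.ndarray) -> float:
    vx = x.var()
    if vx == 0.0 or y.var() == 0.0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def simulate_proteins(
    expression: dict[str, FeatureMatrix],
    genotypes: GenotypeMatrix,
    truth: TruthTable,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    module_factors: Optional[pd.DataFrame] = None,
) -> FeatureMatrix:
    """Plasma proteins from seed transmission, direct cis effects and modules.

    When a protein has a target genetic variance fraction ``f`` in the
    truth table, the direct cis effect is solved from the variance
    decomposition: writing the protein without direct effect as
    ``P0 = a*G + R`` with ``R`` the empirical OLS residual on the causal
    dosage ``G``, the total slope ``b = a + gamma`` must satisfy
    ``b^2 Var(G) = f/(1-f) * Var(R)``. Realized fractions (empirical R^2)
    are recorded in ``truth.realized_genetic_variance_fraction``.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed + 3)
    if module_factors is None:
        # caller should share factors with simulate_expression; standalone use
        # draws fresh factors (module->protein links then bypass expression)
        module_factors = _module_factors(truth, config, rng)

    n = config.n_samples
    proteins = config.protein_ids
    genes = config.gene_ids
    out = np.empty((n, len(proteins)))
    truth.pure_noise_proteins = []

    for pi, p_id in enumerate(proteins):
        g = genes[pi]
        base = np.zeros(n)
        has_signal = False
        for t in config.tissues:
            w = truth.seed_weights.get((p_id, t), 0.0)
            if w != 0.0 and t in expression and g in expression[t].columns:
                base += w * expression[t][g].to_numpy(float)
                has_signal = True
        for (pp, mod), eff in truth.protein_module_effects.items():
            if pp == p_id and eff != 0.0 and mod in module_factors.columns:
                base += eff * module_factors[mod].to_numpy()
                has_signal = True
        noise = rng.normal(
            0.0,
            config.noise_sd if config.protein_noise_sd is None
            else config.protein_noise_sd,
            size=n)
        y = base + noise

        dosage = genotypes.dosages[truth.causal_snp_per_gene[g]].to_numpy(float)
        target = truth.protein_genetic_variance_fraction.get(p_id)
        if target is not None:
            has_signal = True
            vg = dosage.var()
            if vg == 0.0:
                raise ValueError(f"causal SNP for {p_id} is monomorphic")
            a = np.cov(dosage, y)[0, 1] / vg
            resid = y - a * dosage
            b = np.sqrt(target / (1.0 - target) * resid.var() / vg)
            y = resid + b * dosage - resid.mean()

        out[:, pi] = y
        truth.realized_genetic_variance_fraction[p_id] = _univariate_r2(y, dosage)
        if not has_signal:
            truth.pure_noise_proteins.append(p_id)

    return pd.DataFrame(
        out, index=genotypes.sample_ids, columns=pd.Index(proteins, name="protein_id")
    )


def simulate_dataset(config: SimulationConfig,
                     truth: Optional[TruthTable] = None,
                     genetic_variance_fraction: Optional[dict[str, float]] = None):
    """One-call generation of a coherent (genotypes, expression, proteins,
    truth, module_factors) bundle sharing a single module-factor draw."""
    rng = np.random.default_rng(config.rng_seed)
    genotypes = simulate_genotypes(config, rng)
    if truth is None:
        truth = make_truth(config, rng,
                           genetic_variance_fraction=genetic_variance_fraction)
    factors = _module_factors(truth, config, rng)
    expression = simulate_expression(genotypes, truth, config, rng,
                                     module_factors=factors)
    proteins = simulate_proteins(expression, genotypes, truth, config, rng,
                                 module_factors=factors)
    return genotypes, expression, proteins, truth, factors


def simulate_summary_pair(
    scenario: str,
    region_size: int,
    n1: int,
    n2: int,
    effect_z: float = 8.0,
    rng_seed: int = 0,
):
    """Paired per-SNP summary statistics for colocalization testing.

    Scenarios: ``shared`` (one causal SNP, same index in both traits),
    ``distinct`` (different causal SNPs, uncorrelated), ``single_trait``
    (causal in trait 1 only), ``null`` (no association). Effects are on
    the standardized scale: var(beta) = 1/n, causal mean |z| = effect_z.
    """
    from plasmanet.coloc import SummaryStats

    if region_size < 1:
        raise ValueError("region_size must be >= 1")
    if scenario == "distinct" and region_size < 2:
        raise ValueError("distinct scenario needs region_size >= 2")
    if scenario not in {"shared", "distinct", "single_trait", "null"}:
        raise ValueError(f"unknown scenario {scenario!r}")

    rng = np.random.default_rng(rng_seed)
    k = region_size
    positions = np.arange(1, k + 1) * 1_000
    snp_ids = [f"rs{j + 1:05d}" for j in range(k)]
    maf = rng.uniform(0.05, 0.5, size=k)

    z1 = np.zeros(k)
    z2 = np.zeros(k)
    if scenario == "shared":
        c = k // 2
        z1[c] = effect_z
        z2[c] = effect_z
    elif scenario == "distinct":
        c1, c2 = rng.choice(k, size=2, replace=False)
        z1[c1] = effect_z
        z2[c2] = effect_z
    elif scenario == "single_trait":
        z1[k // 2] = effect_z

    def build(z_true: np.ndarray, n: int) -> SummaryStats:
        varbeta = np.full(k, 1.0 / n)
        beta = z_true * np.sqrt(varbeta) + rng.normal(0.0, np.sqrt(varbeta))
        return SummaryStats(pd.DataFrame({
            "snp_id": snp_ids, "position": positions,
            "beta": beta, "varbeta": varbeta, "maf": maf, "n": n,
        }))

    return build(z1, n1), build(z2, n2)


def write_dataset(out_dir, config: SimulationConfig, genotypes: GenotypeMatrix,
                  expression: dict[str, FeatureMatrix], proteins: FeatureMatrix,
                  truth: TruthTable) -> None:
    """Write the bundle in the package's on-disk conventions.

    Dosages as a "-012" TSV (rows SNPs, columns samples), expression and
    proteins as features x samples TSVs, gene annotation as BED (0-based
    half-open, one row per TSS), truth as JSON, plus a sample manifest.
    """
    from plasmanet import preprocess

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    preprocess.write_dosage(out / "genotypes.tsv", genotypes)
    for t, mat in expression.items():
        preprocess.write_matrix(out / f"expression_{t}.tsv", mat)
    preprocess.write_matrix(out / "proteins.tsv", proteins)
    (out / "truth.json").write_text(truth.to_json())
    (out / "samples.txt").write_text("\n".join(config.sample_ids) + "\n")

    rows = []
    for gi, g in enumerate(config.gene_ids):
        tss = gi * GENE_SPACING + 500_000
        rows.append(f"1\t{tss - 1}\t{tss}\t{g}")
    (out / "genes.bed").write_text("\n".join(rows) + "\n")
    (out / "config.json").write_text(json.dumps(asdict(config), indent=1))
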
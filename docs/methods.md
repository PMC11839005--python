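# Methods

This note records the models, parameter choices and caveats behind
`plasmanet`, in the order data flows through the pipeline.

## Synthetic cohort generator

The generator exists so that every analysis stage can be checked against
a planted truth. It emulates a mid-sized multi-tissue proteogenomic
cohort; defaults are 500 samples, 200 genes × 7 tissues, 50 SNPs per
gene, 20 co-expression modules of 10 members.

**Genotypes.** Dosages are drawn by thresholding a latent standard
Gaussian at the Hardy–Weinberg cumulative genotype frequencies
(1−p)² and (1−p)² + 2p(1−p), with per-SNP allele frequency p uniform on
[maf_low, maf_high] = [0.05, 0.5]. Linkage disequilibrium comes from
AR(1) correlation (ld_rho, default 0.8) between latent variables inside
blocks of 10 adjacent SNPs; blocks restart at gene boundaries so genes
are mutually independent. This "thresholded Gaussian copula" is the
simplest generator whose dosage-scale LD can be computed independently
(by Monte-Carlo integration of the copula), which the tests exploit. No
missing genotypes are generated; the analysis assumes complete SNPs and
removes any SNP with missingness.

Genes are laid out 1 Mb apart with the TSS at the centre of each gene's
SNP run (SNPs every 2 kb), so ±500 kb cis windows never overlap between
genes and every SNP falls inside exactly one window.

**Expression.** Gene g in tissue t is
β(g,t)·dosage(causal SNP) + loading·F_m + N(0, σ), where the causal SNP
is the central SNP of the gene's run, β(g,t) ~ N(0, eqtl_effect_sd²)
(default sd 0.5), F_m is a standard-normal per-sample module factor
shared by all members of module m, the loading is 1, and σ = 1. Planting
the eigengene effect through a latent factor (rather than through
individual member genes) keeps "network drives protein" separable from
"seed gene drives protein" in recovery tests.

**Proteins.** One protein per gene:
P = Σ_t w(p,t)·expr(seed gene, t) + γ·dosage + Σ_m e(p,m)·F_m + N(0, σp).
Default truth tables give each protein transmission from one random
tissue (weight uniform on [0.3, 1.0]) and one module effect
N(0, 0.5²). When a target cis-genetic variance fraction f is planted,
the direct effect γ is solved from the empirical decomposition
P0 = a·G + R (R the OLS residual of the γ-free protein on the causal
dosage G): the total slope b = a + γ satisfies b²Var(G) = f/(1−f)·Var(R).
The realized fraction (empirical R²) is recorded back into the truth
table; at n = 10,000 it matches the target within ±0.03. `protein_noise_sd`
exists separately from the expression noise so the noise-free
transmission limit stays testable while expression remains continuous.

**Noise model caveat.** Real NPX measurement error is not characterized
here; Gaussian noise is an assumption of convenience, not a claim about
proximity-extension assay error structure. The generator also omits
realistic human LD maps, population structure, relatedness and
imputation uncertainty, so passing recovery tests demonstrates
correctness of the statistical machinery under the stated model, not
robustness to those real-data complications.

**Summary-statistic pairs** for colocalization place a causal variant of
standardized effect |z| (default 8) at the same SNP (shared), different
SNPs (distinct), one trait only, or nowhere (null); var(β̂) = 1/n and
SNPs are mutually independent — no LD inside the region, which makes the
scenario labels exact.

## Preprocessing

Matrices are sample-major in memory; on disk, dosage files follow the
"-012" convention (rows SNPs) and expression/protein TSVs are
features × samples. Positions are 1-based inclusive internally; BED is
converted on read (interval end = TSS). Covariate adjustment replaces
each feature by its OLS residual on [1, covariates] — the standard
pre-adjustment of NPX values for batch principal components, age and
sex. The number of batch PCs is a caller decision (it is dataset
specific); residualization is idempotent and leaves residuals orthogonal
to every covariate by construction. Zero-variance features are dropped
with a logged warning rather than silently propagating NaNs.

## cis-QTL mapping

Simple regression per (SNP, feature) pair with intercept, t-statistics
on n−2 df, two-sided p. Dosages are deliberately *not* standardized:
betas are per-allele effects, so eQTL and pQTL betas are directly
comparable in the coherence analysis. FDR is Benjamini–Hochberg at 5%,
by default globally across all cis pairs of a phenotype class (per
tissue for eQTLs; one family for pQTLs), with a per-feature scope
available for sensitivity analysis. Records are stably sorted by
(p, snp_id, feature_id) before correction so ties resolve
deterministically. Constant-dosage pairs within the analysis samples are
skipped and counted.

## QTL integration

**Coherence.** The max/difference rule is algebraically equivalent to
sign logic away from ties; ties (m = d or m = 0, reachable only when a
beta is exactly zero) are classified divergent — the conservative choice
on a measure-zero set — and flagged. When a protein shares several
significant SNPs with a tissue, the representative SNP minimizes
max(p_e, p_p), i.e. the SNP most confidently significant in *both*
analyses; "shared" always means the same SNP id significant in both
record sets.

**LD pruning** is greedy: best p first, removing neighbours with
|Pearson r| > 0.8 of dosages. The absolute value treats negative LD as
equally redundant. The procedure is deterministic (ties by SNP id).

**Variance explained** is the adjusted R² of the protein on all pruned
significant dosages plus intercept. A protein with no significant pSNP
is *undefined*, never imputed as zero — imputing zeros would bias any
downstream average of genetic contributions. Residual collinearity
surviving the LD threshold is resolved by dropping trailing SNPs with a
log message. Adjusted R² may legitimately be slightly negative under the
null.

## Colocalization

Per-SNP Wakefield log-ABFs (prior effect sd 0.15 for quantitative
traits) enter the standard five-hypothesis enumeration with priors
p1 = p2 = 1e-4, p12 = 1e-5 — the canonical single-variant defaults,
used because the upstream analysis specifies the method but not the
priors; all are overridable. Sums use log-sum-exp and the H3 term
S1·S2 − S12 is computed by log-space subtraction, so |z| ≈ 40 stays
finite and a single-SNP region yields PP.H3 = 0 exactly. Traits are
aligned on shared SNP ids; alleles are assumed consistently oriented
(an optional strict mode errors when MAF differs by > 0.05 between
traits). The colocalization call is PP.H4 > 0.5. The analysis region is
±100 kb of the TSS — intentionally narrower than the ±500 kb QTL
discovery window, which it inherits from the upstream design. SuSiE-style
multi-causal colocalization and reference-panel allele harmonization are
out of scope.

## Seed-gene association

Spearman rho is the Pearson correlation of average ranks; p-values use
the t approximation (matching common implementations at cohort-scale n);
an exact enumeration over all n! pairings is available for n ≤ 10.
Storey–Tibshirani q-values estimate π0 on the λ grid 0.05…0.95 (step
0.05) with a cubic smoothing spline evaluated at λ = 0.95, clipped into
(0, 1]; below 100 tests the smoother is unreliable and π0 falls back to
1, making q-values BH-equivalent. The marginal seed-gene family pools
all (tissue, gene, protein) pairs by default (per-tissue scope by flag)
— the pooled choice gives one comparable q scale across tissues.
Negative correlations are retained and labelled, not discarded.

The multivariate model restricts to samples present in *all* datasets
(the joint fit needs one cohort), drops collinear tissue columns with a
warning, and assigns q-values across the protein × tissue coefficient
family. With a single tissue it reduces exactly to simple regression.

## Network association

Eigengenes are computed from expression and membership tables rather
than imported, which keeps the stage testable on synthetic data. Member
profiles are z-scored; the eigengene is the first left-singular-vector
score scaled to unit variance, signed so its mean correlation with
members is non-negative (a determinism convention across linear-algebra
backends, since the SVD sign is arbitrary). Purity ≥ 0.95 (inclusive)
defines tissue-specific modules. The permutation null shuffles the
sample labels of each eigengene independently per round (default 1,000
rounds, seeded), preserving protein–protein correlation structure; the
pooled permuted p-values are uniform to KS < 0.02 at grid size 10,000.
Protein categorization takes, among associations at q ≤ 0.05 across the
seed-gene and eigengene families, the predictor with the largest |rho|
(ties by smaller q, then lexicographic id) and reports its class,
together with overlap flags (seed gene only / GRN / GRN containing the
seed gene).

## Problem sizes used in the test and acceptance runs

Oracle-equivalence checks use 100 random instances of 20–120 samples;
colocalization scenarios use 50-SNP regions at n = 5,000 with |z| = 8
over 50 replicates; variance-explained recovery uses n = 500 with a
planted fraction of 0.20 (50 replicates) and a 200-protein slope check;
calibration grids use 2,000 null SNPs and a 10,000-cell permutation
grid; the end-to-end categorization run uses the full default cohort
(500 × 200 genes × 7 tissues × 50 SNPs/gene × 20 modules) with a
30/30/30 planted three-class design. These sizes give stable recovery
statistics while keeping a full run to minutes on one CPU.

## Known limitations

- Real-data counts from any particular cohort are not reproducible here;
  the pipeline's guarantees are oracle equivalence and planted-truth
  recovery under the generator's model.
- The coherence rule's multi-tissue aggregation is implemented pairwise
  (per-tissue eQTL beta vs pQTL beta); a per-protein summary across
  tissues is derivable by grouping the output table.
- Trans-QTLs, covariate-in-model QTL regression, conditional analysis,
  WGCNA module inference and key-driver analysis are out of scope;
  module memberships are inputs.
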
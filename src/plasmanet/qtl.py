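"""cis-eQTL / cis-pQTL mapping by per-SNP simple linear regression.

Each phenotype (tissue transcript or plasma protein) is regressed on the
additive dosage of every SNP inside a ±500 kb window around the gene's
TSS, with an intercept; two-sided p-values come from the t distribution
with n-2 degrees of freedom. Multiple testing is controlled by
Benjamini–Hochberg at FDR 5%, globally across all cis pairs of a
phenotype class by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from plasmanet.core import FeatureMatrix, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = ["CisWindow", "define_cis_windows", "filter_snps", "map_cis_qtl",
           "apply_fdr", "QTL_COLUMNS"]

DEFAULT_WINDOW = 500_000

QTL_COLUMNS = ["snp_id", "feature_id", "tissue", "beta", "se", "tstat", "p", "fdr"]


@dataclass(frozen=True)
class CisWindow:
    """±width window around a gene's TSS, 1-based inclusive on both ends."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


def define_cis_windows(annotation: pd.DataFrame,
                       width: int = DEFAULT_WINDOW) -> dict[str, CisWindow]:
    """One window per annotated gene: [max(1, tss-width), tss+width].

    ``annotation`` is the frame from :func:`plasmanet.preprocess.read_annotation`
    (index gene_id, columns chrom, tss). Genes with a missing TSS are
    skipped with a warning.
    """
    windows: dict[str, CisWindow] = {}
    for gene_id, row in annotation.iterrows():
        if pd.isna(row["tss"]):
            logger.warning("gene %s has no TSS; skipped", gene_id)
            continue
        tss = int(row["tss"])
        windows[str(gene_id)] = CisWindow(
            gene_id=str(gene_id), chrom=str(row["chrom"]),
            start=max(1, tss - width), end=tss + width,
        )
    return windows


def filter_snps(genotypes: GenotypeMatrix, maf_min: float = 0.05) -> GenotypeMatrix:
    """Keep complete SNPs with MAF >= maf_min.

    MAF is min(p, 1-p) with p = mean(dosage)/2. Any SNP with a missing
    value in any sample is removed regardless of frequency.
    """
    complete = genotypes.dosages.notna().all(axis=0)
    maf = genotypes.maf()
    keep = complete & (maf >= maf_min)
    removed = int((~keep).sum())
    if removed:
        logger.info("filter_snps: removed %d of %d SNPs", removed,
                    genotypes.n_snps)
    return genotypes.subset_snps(genotypes.snp_ids[keep])


def _simple_ols_grid(y: np.ndarray, X: np.ndarray):
    """Vectorized per-column simple regression of y on each column of X.

    Returns (beta, se, t, p, keep) where ``keep`` flags columns with
    non-zero dosage variance; all outputs are over the kept columns.
    """
    n = y.shape[0]
    xm = X.mean(axis=0)
    xc = X - xm
    sxx = (xc * xc).sum(axis=0)
    keep = sxx > 0
    xc = xc[:, keep]
    sxx = sxx[keep]
    yc = y - y.mean()
    sxy = xc.T @ yc
    beta = sxy / sxx
    syy = float(yc @ yc)
    rss = syy - beta * sxy
    rss = np.maximum(rss, 0.0)
    df = n - 2
    s2 = rss / df
    se = np.sqrt(s2 / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return beta, se, t, p, keep


def map_cis_qtl(
    genotypes: GenotypeMatrix,
    phenotypes: FeatureMatrix,
    windows: dict[str, CisWindow],
    feature_to_gene: dict[str, str] | None = None,
    tissue: str = "plasma",
) -> pd.DataFrame:
    """Test every (SNP, feature) pair with the SNP in the feature's window.

    ``feature_to_gene`` maps phenotype columns to annotated genes (identity
    by default, the transcript case; for proteins pass the protein→gene
    map). Samples must already be harmonized. SNPs whose dosage is
    constant within the analysis samples are skipped and counted in the
    log. Returns a frame with columns snp_id, feature_id, tissue, beta,
    se, tstat, p (no FDR yet; see :func:`apply_fdr`).
    """
    if not genotypes.sample_ids.equals(phenotypes.index):
        raise ValueError("samples not harmonized between genotypes and phenotypes")
    n = genotypes.n_samples
    if n < 4:
        raise ValueError("need at least 4 samples for n-2 df inference")

    chrom = genotypes.snp_info["chrom"].to_numpy(str)
    pos = genotypes.snp_info["pos"].to_numpy(np.int64)
    snp_ids = genotypes.snp_ids.to_numpy()
    dosage_all = genotypes.dosages.to_numpy(float)

    frames = []
    skipped = 0
    for feature in phenotypes.columns:
        gene = (feature_to_gene or {}).get(feature, feature)
        win = windows.get(gene)
        if win is None:
            continue
        in_win = (chrom == win.chrom) & (pos >= win.start) & (pos <= win.end)
        if not in_win.any():
            continue
        y = phenotypes[feature].to_numpy(float)
        beta, se, t, p, keep = _simple_ols_grid(y, dosage_all[:, in_win])
        skipped += int((~keep).sum())
        frames.append(pd.DataFrame({
            "snp_id": snp_ids[in_win][keep],
            "feature_id": feature,
            "tissue": tissue,
            "beta": beta, "se": se, "tstat": t, "p": p,
        }))
    if skipped:
        logger.info("map_cis_qtl: skipped %d constant-dosage pairs", skipped)
    if not frames:
        return pd.DataFrame(columns=QTL_COLUMNS[:-1])
    return pd.concat(frames, ignore_index=True)


def apply_fdr(records: pd.DataFrame, alpha: float = 0.05,
              scope: str = "global") -> pd.DataFrame:
    """Benjamini–Hochberg step-up; adds ``fdr`` and ``significant`` columns.

    ``scope='global'`` corrects over all records at once (the default
    operating point); ``scope='per_feature'`` corrects within each
    feature_id separately. Records are stably sorted by (p, snp_id,
    feature_id) first so ties resolve deterministically.
    """
    if scope not in {"global", "per_feature"}:
        raise ValueError(f"unknown scope {scope!r}")
    records = records.sort_values(
        ["p", "snp_id", "feature_id"], kind="stable").reset_index(drop=True)
    if records.empty:
        out = records.copy()
        out["fdr"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
        return out
    out = records.copy()
    if scope == "global":
        _, fdr, *_ = multipletests(out["p"].to_numpy(), method="fdr_bh")
        out["fdr"] = fdr
    else:
        out["fdr"] = np.nan
        for _, idx in out.groupby("feature_id").groups.items():
            _, fdr, *_ = multipletests(out.loc[idx, "p"].to_numpy(),
                                       method="fdr_bh")
            out.loc[idx, "fdr"] = fdr
    out["significant"] = out["fdr"] <= alpha
    return out
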
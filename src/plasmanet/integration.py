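"""Overlap of eQTLs with pQTLs, allelic coherence, and variance explained.

A shared cis-QTL is the same SNP significant both for a protein in plasma
and for the protein's coding gene in a tissue. The coherence rule
compares the two allelic effects: with m = max(beta_e, beta_p) and
d = |beta_e - beta_p|, a negative m means both effects are negative
(negatively coherent); a positive m greater than d means both are
positive (positively coherent); a positive m smaller than d means the
smaller effect is negative (divergent). Per-protein cis-genetic variance
explained is the adjusted R^2 of a joint regression on LD-pruned
significant pSNPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from plasmanet.core import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = ["CoherenceCall", "VarianceExplained", "overlap_qtls",
           "classify_coherence", "coherence_table", "ld_prune",
           "variance_explained"]

POSITIVE = "positively_coherent"
NEGATIVE = "negatively_coherent"
DIVERGENT = "divergent"


@dataclass(frozen=True)
class CoherenceCall:
    snp_id: str
    gene_id: str
    tissue: str
    beta_e: float
    beta_p: float
    call: str
    tie: bool = False


@dataclass(frozen=True)
class VarianceExplained:
    """Adjusted R^2 of protein on its independent significant pSNPs.

    ``r2_adjusted`` is None when the protein has no significant pSNP —
    undefined, never imputed as zero. Adjusted R^2 may be negative.
    """

    protein_id: str
    n_independent_snps: int
    r2_adjusted: Optional[float]


def classify_coherence(beta_e: float, beta_p: float) -> str:
    """Allelic-coherence call for one (eQTL beta, pQTL beta) pair.

    Equivalent to the sign logic "same sign => coherent (by the shared
    sign), opposite signs => divergent" away from the tie set m = d or
    m = 0 (only reachable when a beta is exactly zero); ties are called
    divergent, the conservative choice on a measure-zero set.
    """
    if not (np.isfinite(beta_e) and np.isfinite(beta_p)):
        raise ValueError("coherence requires finite betas")
    m = max(beta_e, beta_p)
    d = abs(beta_e - beta_p)
    if m < 0:
        return NEGATIVE
    if m > 0 and m > d:
        return POSITIVE
    return DIVERGENT


def overlap_qtls(
    eqtl_by_tissue: dict[str, pd.DataFrame],
    pqtl_records: pd.DataFrame,
    protein_to_gene: dict[str, str],
) -> tuple[dict[str, set[str]], pd.DataFrame]:
    """Per-protein tissue-sharing sets of shared cis-e/pQTL SNPs.

    A tissue enters a protein's sharing set when at least one SNP is
    FDR-significant both for the protein (pQTL) and for the protein's
    coding gene in that tissue (eQTL). Also returns UpSet-style counts:
    for every observed tissue combination, the number of proteins whose
    sharing set equals exactly that combination.
    """
    sig_p = pqtl_records[pqtl_records["significant"]]
    psnps = {prot: set(grp["snp_id"])
             for prot, grp in sig_p.groupby("feature_id")}

    sharing: dict[str, set[str]] = {}
    for protein, snps in psnps.items():
        gene = protein_to_gene.get(protein)
        if gene is None:
            continue
        tissues = set()
        for tissue, erecs in eqtl_by_tissue.items():
            sig_e = erecs[(erecs["significant"]) & (erecs["feature_id"] == gene)]
            if snps & set(sig_e["snp_id"]):
                tissues.add(tissue)
        sharing[protein] = tissues

    combos = pd.Series(
        ["+".join(sorted(t)) if t else "(plasma only)" for t in sharing.values()]
    ).value_counts().rename_axis("tissue_set").reset_index(name="n_proteins")
    return sharing, combos


def coherence_table(
    eqtl_by_tissue: dict[str, pd.DataFrame],
    pqtl_records: pd.DataFrame,
    protein_to_gene: dict[str, str],
) -> pd.DataFrame:
    """Per-(protein, tissue) coherence calls on shared significant SNPs.

    For each protein and tissue with at least one shared significant SNP,
    the representative SNP is the shared one minimizing max(p_e, p_p)
    (ties broken by snp_id), and the call applies the rule to its two
    betas. A per-protein summary across tissues can be derived by
    grouping the output.
    """
    sig_p = pqtl_records[pqtl_records["significant"]]
    rows = []
    for protein, pgrp in sig_p.groupby("feature_id"):
        gene = protein_to_gene.get(protein)
        if gene is None:
            continue
        p_by_snp = pgrp.set_index("snp_id")
        for tissue, erecs in eqtl_by_tissue.items():
            egrp = erecs[(erecs["significant"]) & (erecs["feature_id"] == gene)]
            shared = sorted(set(p_by_snp.index) & set(egrp["snp_id"]))
            if not shared:
                continue
            e_by_snp = egrp.set_index("snp_id")
            worst = [(max(e_by_snp.at[s, "p"], p_by_snp.at[s, "p"]), s)
                     for s in shared]
            _, snp = min(worst)
            be = float(e_by_snp.at[snp, "beta"])
            bp = float(p_by_snp.at[snp, "beta"])
            m, d = max(be, bp), abs(be - bp)
            rows.append({
                "protein_id": protein, "gene_id": gene, "tissue": tissue,
                "snp_id": snp, "beta_e": be, "beta_p": bp,
                "call": classify_coherence(be, bp),
                "tie": bool(m == d or m == 0.0),
            })
    return pd.DataFrame(
        rows, columns=["protein_id", "gene_id", "tissue", "snp_id",
                       "beta_e", "beta_p", "call", "tie"])


def ld_prune(
    snp_ids,
    genotypes: GenotypeMatrix,
    p_values,
    r_threshold: float = 0.8,
) -> list[str]:
    """Greedy LD pruning: best p first, drop |Pearson r| > threshold.

    SNPs are sorted by p ascending (ties by snp_id for determinism); the
    best remaining SNP is kept and every remaining SNP whose dosage
    correlation with it exceeds the threshold in absolute value is
    removed. Returns kept SNP ids in selection order.
    """
    snp_ids = list(snp_ids)
    if not snp_ids:
        return []
    pv = pd.Series(np.asarray(p_values, float), index=snp_ids)
    order = sorted(snp_ids, key=lambda s: (pv[s], s))
    X = genotypes.dosages.loc[:, order].to_numpy(float)
    Xc = X - X.mean(axis=0)
    norms = np.sqrt((Xc * Xc).sum(axis=0))
    norms[norms == 0] = np.inf  # constant dosage correlates with nothing

    kept: list[str] = []
    alive = np.ones(len(order), dtype=bool)
    for i in range(len(order)):
        if not alive[i]:
            continue
        kept.append(order[i])
        r = (Xc[:, i] @ Xc) / (norms[i] * norms)
        alive &= ~(np.abs(r) > r_threshold)
        alive[i] = False
    return kept


def variance_explained(
    protein: pd.Series,
    pqtl_records: pd.DataFrame,
    genotypes: GenotypeMatrix,
    r_threshold: float = 0.8,
) -> VarianceExplained:
    """Cis-genetic variance explained for one protein.

    LD-prunes the protein's FDR-significant pSNPs, then fits a joint OLS
    of the protein on all independent dosages plus intercept; reports
    adjusted R^2 = 1 - (1-R^2)(n-1)/(n-k-1). With no significant pSNP the
    result is undefined (r2_adjusted None). Near-singular designs after
    pruning drop offending SNPs with a log message.
    """
    name = str(protein.name)
    sig = pqtl_records[(pqtl_records["significant"])
                       & (pqtl_records["feature_id"] == name)]
    if sig.empty:
        return VarianceExplained(name, 0, None)
    kept = ld_prune(sig["snp_id"].tolist(), genotypes,
                    sig["p"].tolist(), r_threshold)

    y = protein.to_numpy(float)
    n = len(y)
    X = genotypes.dosages.loc[:, kept].to_numpy(float)
    # guard against residual collinearity surviving the LD threshold
    design = np.column_stack([np.ones(n), X])
    while np.linalg.matrix_rank(design) < design.shape[1] and len(kept) > 1:
        logger.info("variance_explained(%s): dropping %s (singular design)",
                    name, kept[-1])
        kept = kept[:-1]
        X = genotypes.dosages.loc[:, kept].to_numpy(float)
        design = np.column_stack([np.ones(n), X])
    k = len(kept)
    if n <= k + 1:
        raise ValueError(f"{name}: n={n} too small for k={k} SNPs")

    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0.0:
        return VarianceExplained(name, k, None)
    r2 = 1.0 - float(resid @ resid) / tss
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
    return VarianceExplained(name, k, r2_adj)
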
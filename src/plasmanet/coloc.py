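"""Approximate-Bayes-factor colocalization for two quantitative traits.

Given per-SNP summary statistics (beta, var(beta)) for two traits over a
shared region, the method computes Wakefield's approximate Bayes factor
per SNP and trait, then the posterior probabilities of five hypotheses:

* H0 — no association with either trait;
* H1 / H2 — association with trait 1 / trait 2 only;
* H3 — both traits associated, two distinct causal variants;
* H4 — both traits associated, one shared causal variant.

For SNP j with z^2 = beta^2/varbeta and shrinkage r = W/(W + varbeta),
W the prior effect variance, the log-ABF is
``0.5*log(1-r) + 0.5*z^2*r``. Hypothesis weights follow the standard
single-causal-variant enumeration with per-SNP priors (p1, p2, p12); all
sums are log-sum-exp stabilized so |z| ~ 40 stays finite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

__all__ = ["SummaryStats", "ColocPriors", "ColocPosterior", "region_select",
           "prefilter_pairs", "log_abf", "coloc_abf", "coloc_gwas"]

SUMMARY_COLUMNS = ["snp_id", "position", "beta", "varbeta", "maf", "n"]


class SummaryStats:
    """Per-SNP association summary statistics for one trait over a region.

    Wraps a frame with columns snp_id, position (1-based), beta, varbeta
    (squared standard error), maf, n. SNP ids must be unique, varbeta
    positive, maf in (0, 0.5].
    """

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in SUMMARY_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"summary statistics missing columns {missing}")
        table = table.reset_index(drop=True)
        if table["snp_id"].duplicated().any():
            raise ValueError("duplicate SNP ids in summary statistics")
        if (table["varbeta"] <= 0).any():
            raise ValueError("varbeta must be positive")
        maf = table["maf"]
        if ((maf <= 0) | (maf > 0.5)).any():
            raise ValueError("maf must lie in (0, 0.5]")
        self.table = table

    def __len__(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> pd.Index:
        return pd.Index(self.table["snp_id"])

    @classmethod
    def read_tsv(cls, path) -> "SummaryStats":
        return cls(pd.read_csv(path, sep="\t"))

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ColocPriors:
    """Per-SNP priors: p1/p2 single-trait, p12 shared; W = prior_sd^2.

    Defaults are the canonical single-variant values for quantitative
    traits: p1 = p2 = 1e-4, p12 = 1e-5, prior effect sd 0.15.
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    prior_sd: float = 0.15

    def __post_init__(self) -> None:
        if not 0 < self.p12 <= min(self.p1, self.p2):
            raise ValueError("need 0 < p12 <= min(p1, p2)")
        if self.p1 + self.p2 + self.p12 >= 1:
            raise ValueError("p1 + p2 + p12 must be < 1")
        if self.prior_sd <= 0:
            raise ValueError("prior_sd must be positive")


@dataclass(frozen=True)
class ColocPosterior:
    pp_h0: float
    pp_h1: float
    pp_h2: float
    pp_h3: float
    pp_h4: float

    @property
    def colocalized(self) -> bool:
        return self.pp_h4 > 0.5

    def as_array(self) -> np.ndarray:
        return np.array([self.pp_h0, self.pp_h1, self.pp_h2,
                         self.pp_h3, self.pp_h4])

    def as_dict(self) -> dict[str, float]:
        return {"pp_h0": self.pp_h0, "pp_h1": self.pp_h1, "pp_h2": self.pp_h2,
                "pp_h3": self.pp_h3, "pp_h4": self.pp_h4}


def region_select(stats: SummaryStats, tss: int,
                  half_width: int = 100_000) -> SummaryStats:
    """SNPs with |position - tss| <= half_width, both ends inclusive."""
    t = stats.table
    keep = (t["position"] - tss).abs() <= half_width
    sub = t[keep].reset_index(drop=True)
    if sub.empty:
        logger.warning("region_select: no SNPs within %d of %d", half_width, tss)
    return SummaryStats(sub)


def prefilter_pairs(
    eqtl_by_tissue: dict[str, pd.DataFrame],
    pqtl_records: pd.DataFrame,
    protein_to_gene: dict[str, str],
) -> list[tuple[str, str, str]]:
    """(gene, protein, tissue) triples with >=1 SNP significant in both.

    Matching means the same SNP id carries an FDR-significant eQTL for the
    protein's coding gene and an FDR-significant pQTL for the protein.
    """
    sig_p = pqtl_records[pqtl_records["significant"]]
    psnps = {prot: set(g["snp_id"]) for prot, g in sig_p.groupby("feature_id")}
    pairs = []
    for tissue, erecs in eqtl_by_tissue.items():
        sig_e = erecs[erecs["significant"]]
        esnps = {gene: set(g["snp_id"]) for gene, g in sig_e.groupby("feature_id")}
        for protein, snps in psnps.items():
            gene = protein_to_gene.get(protein)
            if gene in esnps and snps & esnps[gene]:
                pairs.append((gene, protein, tissue))
    return sorted(pairs)


def log_abf(beta, varbeta, prior_sd: float = 0.15):
    """Wakefield log approximate Bayes factor (association vs null).

    log ABF = 0.5*log(1 - r) + 0.5*z^2*r with z^2 = beta^2/varbeta and
    r = W/(W + varbeta), W = prior_sd^2. Vectorized over arrays.
    """
    beta = np.asarray(beta, float)
    varbeta = np.asarray(varbeta, float)
    if (varbeta <= 0).any():
        raise ValueError("varbeta must be positive")
    W = prior_sd * prior_sd
    r = W / (W + varbeta)
    z2 = beta * beta / varbeta
    out = 0.5 * np.log1p(-r) + 0.5 * z2 * r
    return float(out) if out.ndim == 0 else out


def _logdiffexp(a: float, b: float) -> float:
    """log(e^a - e^b) for a >= b; -inf when the difference underflows."""
    if b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def coloc_abf(stats1: SummaryStats, stats2: SummaryStats,
              priors: ColocPriors = ColocPriors(),
              strict_maf_check: bool = False) -> ColocPosterior:
    """Posterior over H0..H4 for two traits, aligned on shared SNP ids.

    With per-SNP log-ABFs l1, l2 over the k shared SNPs, the unnormalized
    hypothesis weights are (1, p1*S1, p2*S2, p1*p2*(S1*S2 - S12),
    p12*S12) where S1 = sum e^l1, S2 = sum e^l2, S12 = sum e^(l1+l2);
    the H3 sum excludes same-SNP configurations by subtraction. All
    computed in log space. With a single shared SNP pp_h3 is exactly 0.
    """
    t1 = stats1.table.set_index("snp_id")
    t2 = stats2.table.set_index("snp_id")
    shared = t1.index.intersection(t2.index)
    if len(shared) < 1:
        raise ValueError("no shared SNPs between traits")
    t1, t2 = t1.loc[shared], t2.loc[shared]
    if strict_maf_check:
        dmaf = (t1["maf"] - t2["maf"]).abs()
        if (dmaf > 0.05).any():
            bad = shared[dmaf > 0.05][0]
            raise ValueError(f"MAF discrepancy > 0.05 at {bad} between traits")

    l1 = log_abf(t1["beta"].to_numpy(), t1["varbeta"].to_numpy(), priors.prior_sd)
    l2 = log_abf(t2["beta"].to_numpy(), t2["varbeta"].to_numpy(), priors.prior_sd)

    lse1 = float(logsumexp(l1))
    lse2 = float(logsumexp(l2))
    lse12 = float(logsumexp(l1 + l2))

    lw = np.array([
        0.0,
        np.log(priors.p1) + lse1,
        np.log(priors.p2) + lse2,
        np.log(priors.p1) + np.log(priors.p2) + _logdiffexp(lse1 + lse2, lse12),
        np.log(priors.p12) + lse12,
    ])
    pp = np.exp(lw - logsumexp(lw))
    pp /= pp.sum()
    return ColocPosterior(*pp.tolist())


def coloc_gwas(pqtl_stats: SummaryStats, gwas_stats: SummaryStats,
               priors: ColocPriors = ColocPriors(),
               strict_maf_check: bool = False) -> ColocPosterior:
    """Colocalization of a cis-pQTL region with GWAS summary statistics.

    Same machinery as :func:`coloc_abf`; trait 2 is the GWAS trait read
    from the common summary-stats schema.
    """
    return coloc_abf(pqtl_stats, gwas_stats, priors=priors,
                     strict_maf_check=strict_maf_check)
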
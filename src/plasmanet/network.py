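"""Module eigengenes, protein-eigengene association, permutation null.

A co-expression module ("gene-regulatory network", GRN) is a fixed set of
(gene, tissue) members. Its eigengene is the first principal-component
score of the standardized member-expression matrix — one value per
sample, summarizing the module's joint activity. Modules are classed as
tissue-specific when at least 95% of members come from a single tissue
(purity >= 0.95), else cross-tissue. Each plasma protein is associated
with every eigengene by Spearman correlation (q-values over the whole
grid), the empirical null is built by permuting eigengene sample labels,
and each protein is assigned the class of its strongest significant
predictor — seed gene, tissue-specific GRN, or cross-tissue GRN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from plasmanet.core import FeatureMatrix
from plasmanet.seed import qvalues, spearman_grid

logger = logging.getLogger(__name__)

__all__ = ["ModuleDefinition", "Eigengene", "ProteinCategory",
           "compute_eigengene", "classify_module", "eigengene_matrix",
           "correlate_eigengenes", "permutation_null", "categorize_proteins",
           "seedgene_in_module"]

PURITY_THRESHOLD = 0.95
TISSUE_SPECIFIC = "tissue_specific"
CROSS_TISSUE = "cross_tissue"


@dataclass(frozen=True)
class ModuleDefinition:
    module_id: str
    members: frozenset  # of (gene_id, tissue)
    purity: float
    tissue_class: str


@dataclass(frozen=True)
class Eigengene:
    module_id: str
    values: pd.Series  # per-sample, unit variance
    pc1_variance_fraction: float


@dataclass(frozen=True)
class ProteinCategory:
    protein_id: str
    category: str  # seed_gene | tissue_specific_grn | cross_tissue_grn | none
    best_rho: float = np.nan
    best_q: float = np.nan
    best_predictor: str = ""
    overlap: frozenset = field(default_factory=frozenset)


def classify_module(module_id: str, members) -> ModuleDefinition:
    """Purity = largest single-tissue member fraction; class by >= 0.95."""
    members = frozenset(members)
    if not members:
        raise ValueError("empty module")
    counts = pd.Series([t for _, t in members]).value_counts()
    purity = float(counts.iloc[0] / len(members))
    cls = TISSUE_SPECIFIC if purity >= PURITY_THRESHOLD else CROSS_TISSUE
    return ModuleDefinition(module_id, members, purity, cls)


def compute_eigengene(module_id: str, member_expression: pd.DataFrame) -> Eigengene:
    """First-PC summary of a module's standardized member expression.

    Columns are member (gene, tissue) profiles over a common sample set.
    Constant members are dropped; genes are z-scored; the eigengene is
    the first left-singular-vector score rescaled to unit variance, with
    its sign chosen so the mean correlation with members is non-negative.
    """
    if member_expression.shape[1] == 0:
        raise ValueError(f"module {module_id}: no members with expression")
    X = member_expression.to_numpy(float)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError(f"module {module_id}: all members constant")
    if not keep.all():
        logger.warning("module %s: dropping %d constant members",
                       module_id, int((~keep).sum()))
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    U, S, _ = np.linalg.svd(Z, full_matrices=False)
    score = U[:, 0] * S[0]
    score = score / score.std(ddof=0)
    mean_corr = (Z * score[:, None]).mean()
    if mean_corr < 0:
        score = -score
    pc1_frac = float(S[0] ** 2 / (S ** 2).sum())
    return Eigengene(module_id,
                     pd.Series(score, index=member_expression.index),
                     pc1_frac)


def eigengene_matrix(
    expression: dict[str, FeatureMatrix],
    membership: pd.DataFrame,
) -> tuple[FeatureMatrix, dict[str, ModuleDefinition]]:
    """Eigengenes for every module in a membership table.

    ``membership`` has columns module_id, gene_id, tissue. Members whose
    gene is absent from the tissue's expression matrix are ignored (with
    a count in the log). Samples are restricted to those shared by every
    involved tissue. Returns (samples x modules frame of unit-variance
    eigengenes, module definitions keyed by id).
    """
    required = {"module_id", "gene_id", "tissue"}
    if not required <= set(membership.columns):
        raise ValueError(f"membership table needs columns {sorted(required)}")
    tissues = sorted(set(membership["tissue"]) & set(expression))
    shared = None
    for t in tissues:
        idx = expression[t].index
        shared = idx if shared is None else shared.intersection(idx)
    if shared is None or len(shared) == 0:
        raise ValueError("no shared samples across member tissues")
    shared = shared.sort_values()

    eig_cols = {}
    defs: dict[str, ModuleDefinition] = {}
    dropped = 0
    for mod, grp in membership.groupby("module_id"):
        members = [(g, t) for g, t in zip(grp["gene_id"], grp["tissue"])]
        defs[str(mod)] = classify_module(str(mod), members)
        cols = {}
        for g, t in members:
            if t in expression and g in expression[t].columns:
                cols[f"{g}@{t}"] = expression[t].loc[shared, g]
            else:
                dropped += 1
        if not cols:
            logger.warning("module %s has no members with expression; skipped",
                           mod)
            continue
        eig = compute_eigengene(str(mod), pd.DataFrame(cols))
        eig_cols[str(mod)] = eig.values
    if dropped:
        logger.info("eigengene_matrix: %d members without expression", dropped)
    return pd.DataFrame(eig_cols, index=shared), defs


def correlate_eigengenes(
    proteins: FeatureMatrix,
    eigengenes: FeatureMatrix,
    module_classes: dict[str, str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full protein x module Spearman grid with q-values over the grid."""
    shared = proteins.index.intersection(eigengenes.index).sort_values()
    if len(shared) < 4:
        raise ValueError("fewer than 4 shared samples")
    rho, p = spearman_grid(eigengenes.loc[shared], proteins.loc[shared])
    long = pd.DataFrame({
        "predictor_id": np.repeat(rho.index, rho.shape[1]),
        "protein_id": np.tile(rho.columns, rho.shape[0]),
        "rho": rho.to_numpy().ravel(),
        "p": p.to_numpy().ravel(),
    })
    long = long.dropna(subset=["rho"]).reset_index(drop=True)
    cls = module_classes or {}
    long["predictor_class"] = [
        ("tissue_specific_grn"
         if cls.get(m, CROSS_TISSUE) == TISSUE_SPECIFIC else "cross_tissue_grn")
        for m in long["predictor_id"]]
    long["tissue"] = ""
    long["n"] = len(shared)
    long["q"] = qvalues(long["p"].to_numpy())
    long["significant"] = long["q"] <= alpha
    return long[["predictor_id", "predictor_class", "tissue", "protein_id",
                 "rho", "p", "q", "n", "significant"]]


def permutation_null(
    proteins: FeatureMatrix,
    eigengenes: FeatureMatrix,
    n_perm: int = 1000,
    rng_seed: int = 0,
) -> np.ndarray:
    """Pooled p-values of the protein x eigengene grid under label shuffling.

    Each permutation round independently permutes the sample labels of
    every eigengene column (protein-protein correlation structure is
    preserved), recomputes the full Spearman grid, and pools the
    p-values. Reproducible under ``rng_seed``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    shared = proteins.index.intersection(eigengenes.index).sort_values()
    pr = proteins.loc[shared]
    eg = eigengenes.loc[shared].to_numpy(float)
    rng = np.random.default_rng(rng_seed)
    pooled = []
    for _ in range(n_perm):
        perm = np.empty_like(eg)
        for j in range(eg.shape[1]):
            perm[:, j] = eg[rng.permutation(len(shared)), j]
        _, p = spearman_grid(
            pd.DataFrame(perm, index=shared, columns=eigengenes.columns), pr)
        pooled.append(p.to_numpy().ravel())
    return np.concatenate(pooled)


def categorize_proteins(
    seed_records: pd.DataFrame,
    eigengene_records: pd.DataFrame,
    protein_to_gene: dict[str, str] | None = None,
    membership: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> dict[str, ProteinCategory]:
    """Assign each protein the class of its strongest significant predictor.

    Among associations with q <= alpha across both families the winner is
    the largest |rho|; ties break by smaller q, then lexicographic
    predictor id. Proteins with no significant association are 'none'.
    The ``overlap`` field records which of {seed_gene, grn,
    grn_with_seed_gene} apply, mirroring overlap-set summaries.
    """
    cols = ["predictor_id", "predictor_class", "protein_id", "rho", "q",
            "significant"]
    pool = pd.concat([seed_records[cols], eigengene_records[cols]],
                     ignore_index=True)
    proteins = sorted(set(pool["protein_id"]))
    sig = pool[pool["significant"]]

    out: dict[str, ProteinCategory] = {}
    for p_id in proteins:
        mine = sig[sig["protein_id"] == p_id]
        if mine.empty:
            out[p_id] = ProteinCategory(p_id, "none")
            continue
        mine = mine.assign(absrho=mine["rho"].abs()).sort_values(
            ["absrho", "q", "predictor_id"],
            ascending=[False, True, True], kind="stable")
        best = mine.iloc[0]
        overlap = set()
        if (mine["predictor_class"] == "seed_gene").any():
            overlap.add("seed_gene")
        grn_hits = mine[mine["predictor_class"].isin(
            ["tissue_specific_grn", "cross_tissue_grn"])]
        if not grn_hits.empty:
            overlap.add("grn")
            if protein_to_gene is not None and membership is not None:
                gene = protein_to_gene.get(p_id)
                for mod in set(grn_hits["predictor_id"]):
                    if gene is not None and seedgene_in_module(
                            gene, mod, membership):
                        overlap.add("grn_with_seed_gene")
                        break
        out[p_id] = ProteinCategory(
            p_id, str(best["predictor_class"]), float(best["rho"]),
            float(best["q"]), str(best["predictor_id"]), frozenset(overlap))
    return out


def seedgene_in_module(gene_id: str | None, module_id: str,
                       membership: pd.DataFrame) -> bool:
    """True iff any tissue instance of the gene belongs to the module."""
    if gene_id is None:
        logger.warning("seedgene_in_module: unmapped protein gene")
        return False
    grp = membership[membership["module_id"] == module_id]
    return bool((grp["gene_id"] == gene_id).any())
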
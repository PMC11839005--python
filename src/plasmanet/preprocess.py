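"""Reading, writing, sample harmonization and covariate residualization.

On-disk conventions: dosage matrices are "-012" TSVs (rows SNPs, columns
samples); expression and protein matrices are features x samples TSVs;
gene annotation is BED (0-based half-open; the interval end is the TSS) or
GTF; covariates are a samples x covariates TSV. Internally everything is
sample-major (see :mod:`plasmanet.core`), and positions are 1-based.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from plasmanet.core import FeatureMatrix, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_dosage",
    "write_dosage",
    "read_matrix",
    "write_matrix",
    "read_annotation",
    "read_vcf_dosage",
    "read_covariates",
    "harmonize_samples",
    "adjust_covariates",
    "drop_constant_features",
]


def read_dosage(path, strict_012: bool = True) -> GenotypeMatrix:
    """Read a "-012" dosage TSV (rows SNPs, columns samples).

    With ``strict_012`` every entry must be exactly 0, 1 or 2; the first
    offending (SNP, sample) cell is named in the error. Missing values are
    always rejected — SNPs with missingness are expected to be removed
    upstream.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate SNP identifiers")
    if df.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate sample identifiers")
    vals = df.to_numpy(float)
    if np.isnan(vals).any():
        i, j = np.argwhere(np.isnan(vals))[0]
        raise ValueError(f"{path}: missing dosage at SNP {df.index[i]!r}, "
                         f"sample {df.columns[j]!r}")
    if strict_012 and not np.isin(vals, (0.0, 1.0, 2.0)).all():
        bad = ~np.isin(vals, (0.0, 1.0, 2.0))
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: dosage {vals[i, j]!r} outside {{0,1,2}} at SNP "
            f"{df.index[i]!r}, sample {df.columns[j]!r}")
    dosages = df.T
    dosages.index.name = "sample_id"
    dosages.columns.name = "snp_id"
    if strict_012:
        dosages = dosages.astype(np.int8)
    return GenotypeMatrix(dosages=dosages)


def write_dosage(path, genotypes: GenotypeMatrix) -> None:
    """Write dosages in the "-012" convention (rows SNPs, columns samples)."""
    genotypes.dosages.T.to_csv(path, sep="\t", index_label="snp_id")


def read_matrix(path) -> FeatureMatrix:
    """Read a features x samples TSV into a samples x features frame."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate feature identifiers")
    if df.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate sample identifiers")
    out = df.T
    out.index.name = "sample_id"
    return out


def write_matrix(path, matrix: FeatureMatrix) -> None:
    matrix.T.to_csv(path, sep="\t", index_label="feature_id")


def read_annotation(path) -> pd.DataFrame:
    """Read gene TSS annotation from BED or GTF.

    Returns a frame indexed by ``gene_id`` with columns ``chrom`` and
    ``tss`` (1-based). BED intervals are 0-based half-open; the interval
    *end* is taken as the 1-based TSS (so a row ``chr1  999  1000  G1``
    yields tss = 1000). For GTF, ``gene`` features are used, with the TSS
    at ``start`` on '+' strands and ``end`` on '-' strands.
    """
    path = Path(path)
    if path.suffix.lower() in {".gtf", ".gff"}:
        return _read_gtf_annotation(path)
    bed = pd.read_csv(path, sep="\t", header=None, comment="#",
                      usecols=[0, 1, 2, 3],
                      names=["chrom", "start", "end", "gene_id"])
    if bed["gene_id"].duplicated().any():
        dup = bed.loc[bed["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"{path}: duplicate gene_id {dup!r}")
    out = pd.DataFrame({
        "chrom": bed["chrom"].astype(str).to_numpy(),
        "tss": bed["end"].to_numpy(np.int64),
    }, index=pd.Index(bed["gene_id"].to_numpy(), name="gene_id"))
    if (out["tss"] < 1).any():
        raise ValueError(f"{path}: TSS positions must be >= 1")
    return out


def _read_gtf_annotation(path) -> pd.DataFrame:
    import re

    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            m = re.search(r'gene_id "([^"]+)"', f[8])
            if not m:
                continue
            tss = int(f[3]) if f[6] != "-" else int(f[4])
            rows.append((m.group(1), f[0], tss))
    out = pd.DataFrame(rows, columns=["gene_id", "chrom", "tss"])
    if out["gene_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate gene_id in GTF")
    return out.set_index("gene_id")


def read_vcf_dosage(path) -> GenotypeMatrix:
    """Read genotypes from a VCF into an additive dosage matrix.

    Uses the DS FORMAT field when present, else the GT allele count.
    Records lacking both are a hard error; missing genotypes are rejected.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids, chroms, positions, rows = [], [], [], []
    for var in vcf:
        sid = var.ID or f"{var.CHROM}:{var.POS}"
        if "DS" in (var.FORMAT or []):
            dos = np.asarray(var.format("DS"), dtype=float).reshape(-1)
        else:
            gts = var.genotype.array()
            if gts is None:
                raise ValueError(f"{path}: record {sid} has neither GT nor DS")
            alleles = gts[:, :2]
            if (alleles < 0).any():
                raise ValueError(f"{path}: missing genotype at {sid}")
            dos = alleles.sum(axis=1).astype(float)
        if np.isnan(dos).any():
            raise ValueError(f"{path}: missing dosage at {sid}")
        snp_ids.append(sid)
        chroms.append(var.CHROM)
        positions.append(var.POS)
        rows.append(dos)
    if not rows:
        raise ValueError(f"{path}: no variant records")
    dosages = pd.DataFrame(
        np.column_stack(rows),
        index=pd.Index(samples, name="sample_id"),
        columns=pd.Index(snp_ids, name="snp_id"),
    )
    snp_info = pd.DataFrame({"chrom": chroms, "pos": positions},
                            index=dosages.columns)
    return GenotypeMatrix(dosages=dosages, snp_info=snp_info)


def read_covariates(path) -> pd.DataFrame:
    """Samples x covariates TSV; one row per sample, no missing values."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate sample identifiers")
    if df.isna().any().any():
        raise ValueError(f"{path}: missing covariate values")
    return df


def _sample_index(obj) -> pd.Index:
    return obj.sample_ids if isinstance(obj, GenotypeMatrix) else obj.index


def harmonize_samples(*matrices):
    """Restrict all inputs to the intersection of sample ids, common order.

    Accepts any mix of ``FeatureMatrix`` frames, covariate frames and
    ``GenotypeMatrix``; returns them in input order, all with identical
    sample order (sorted intersection). Empty intersection is an error.
    """
    if not matrices:
        raise ValueError("no matrices given")
    shared: pd.Index | None = None
    for m in matrices:
        idx = _sample_index(m)
        shared = idx if shared is None else shared.intersection(idx)
    if shared is None or len(shared) == 0:
        raise ValueError("no samples shared across all inputs")
    shared = shared.sort_values()
    logger.info("harmonize_samples: %d shared samples", len(shared))
    out = []
    for m in matrices:
        if isinstance(m, GenotypeMatrix):
            out.append(m.subset_samples(shared))
        else:
            out.append(m.loc[shared])
    return tuple(out)


def adjust_covariates(matrix: FeatureMatrix, covariates: pd.DataFrame) -> FeatureMatrix:
    """Residualize each feature on [1, covariates] by least squares.

    Mirrors the usual NPX pre-adjustment for batch principal components,
    age and sex: each feature is replaced by its OLS residual, which is
    orthogonal to every covariate column. The design (with intercept) must
    be full column rank; collinear columns are named in the error.
    """
    if not matrix.index.equals(covariates.index):
        matrix, covariates = harmonize_samples(matrix, covariates)
    X = np.column_stack([np.ones(len(matrix)), covariates.to_numpy(float)])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        names = _collinear_columns(X, ["(intercept)"] + list(covariates.columns))
        raise ValueError(f"rank-deficient covariate design; collinear: {names}")
    Y = matrix.to_numpy(float)
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    return pd.DataFrame(resid, index=matrix.index, columns=matrix.columns)


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Greedy identification of columns that do not extend the column space."""
    bad = []
    kept = np.empty((X.shape[0], 0))
    for j, name in enumerate(names):
        cand = np.column_stack([kept, X[:, j]])
        if np.linalg.matrix_rank(cand) == kept.shape[1]:
            bad.append(name)
        else:
            kept = cand
    return bad


def drop_constant_features(matrix: FeatureMatrix) -> FeatureMatrix:
    """Drop zero-variance features (logged); returns the reduced frame."""
    sd = matrix.std(axis=0, ddof=0)
    keep = sd > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("dropping %d zero-variance features", dropped)
    return matrix.loc[:, keep]
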
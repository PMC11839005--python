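"""Seed-gene correlation, Storey q-values, QQ tables, multivariate model.

A "seed gene" is the coding gene of a plasma protein in a given tissue
whose expression correlates significantly (q <= 0.05) with the protein's
plasma level, by Spearman rank correlation. Because the same transcript
can correlate with its protein in many tissues through shared regulation,
a multivariate cross-tissue model re-fits each protein on its transcript
in every tissue jointly (Y = b0 + b1*X1 + ... + bT*XT + e) on the samples
present in all datasets; coefficients surviving adjustment indicate the
transmitting tissue.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import UnivariateSpline

from plasmanet.core import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = ["spearman", "spearman_grid", "qvalues", "correlate_seed_genes",
           "qq_compare", "multivariate_seed_model", "MultivariateFit"]


def spearman(x, y, exact: bool = False) -> tuple[float, float]:
    """Spearman rho and two-sided p for two equal-length vectors.

    rho is the Pearson correlation of average ranks; p uses the
    large-sample t approximation with n-2 df (the default at any n), or,
    with ``exact=True`` and n <= 10, the exact permutation distribution
    of rho enumerated over all n! rank pairings. Constant input is
    undefined and raises.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length 1-d vectors of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: Spearman correlation undefined")
    n = len(x)
    if exact:
        if n > 10:
            raise ValueError("exact permutation p limited to n <= 10")
        return _spearman_exact(x, y)
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def _spearman_exact(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Enumerate all n! pairings of ranks; two-sided p = P(|rho*| >= |rho|)."""
    from itertools import permutations

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho_obs = float(np.corrcoef(rx, ry)[0, 1])
    n = len(x)
    ry_c = (ry - ry.mean()) / ry.std(ddof=0)
    rx_c = (rx - rx.mean()) / rx.std(ddof=0)
    perms = np.array(list(permutations(range(n))))
    rho_null = rx_c[perms] @ ry_c / n
    tol = 1e-12
    p = float((np.abs(rho_null) >= abs(rho_obs) - tol).mean())
    return rho_obs, p


def spearman_grid(left: pd.DataFrame, right: pd.DataFrame):
    """All-pairs Spearman rho and t-approximation p between two frames.

    ``left`` (n x p) and ``right`` (n x q) share row order; returns
    (rho, p) DataFrames of shape p x q. Equivalent to looping
    ``scipy.stats.spearmanr`` over pairs but a single matrix product on
    the standardized average ranks.
    """
    if len(left) != len(right):
        raise ValueError("frames must share sample rows")
    n = len(left)
    if n < 4:
        raise ValueError("need n >= 4 for the t approximation")

    def zrank(df: pd.DataFrame) -> np.ndarray:
        r = stats.rankdata(df.to_numpy(float), axis=0)
        r = r - r.mean(axis=0)
        sd = r.std(axis=0, ddof=0)
        sd[sd == 0] = np.nan  # constant columns -> rho NaN, flagged by caller
        return r / sd

    zl = zrank(left)
    zr = zrank(right)
    rho = zl.T @ zr / n
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.isnan(rho), np.nan, np.clip(p, np.finfo(float).tiny, 1.0))
    p = np.where(np.abs(rho) == 1.0, np.finfo(float).tiny, p)
    return (pd.DataFrame(rho, index=left.columns, columns=right.columns),
            pd.DataFrame(p, index=left.columns, columns=right.columns))


def estimate_pi0(p: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Storey's pi0 (fraction of true nulls) with the spline smoother.

    pi0(lambda) = #{p > lambda} / (m * (1 - lambda)) on the grid
     lambda = 0.05, 0.10, ..., 0.95; a cubic smoothing spline (df ~ 3) is
    evaluated at the largest lambda and clipped into (0, 1].
    """
    p = np.asarray(p, float)
    m = len(p)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    pi0_grid = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    spline = UnivariateSpline(lambdas, pi0_grid, k=3, s=len(lambdas) / 2.0)
    pi0 = float(spline(lambdas[-1]))
    return float(min(max(pi0, 1.0 / m), 1.0))


def qvalues(p, min_m_for_pi0: int = 100) -> np.ndarray:
    """Storey–Tibshirani q-values.

    q_(i) = min_{j >= i} pi0 * m * p_(j) / j over the p-sorted sequence.
    With fewer than ``min_m_for_pi0`` tests the smoother is unreliable
    and pi0 falls back to 1 (Benjamini–Hochberg-equivalent), logged.
    Output is monotone in p and aligned to the input order.
    """
    p = np.asarray(p, float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1] and be non-missing")
    m = len(p)
    if m == 0:
        return np.array([])
    if m < min_m_for_pi0:
        logger.info("qvalues: m=%d < %d, using pi0=1", m, min_m_for_pi0)
        pi0 = 1.0
    else:
        pi0 = estimate_pi0(p)
    order = np.argsort(p, kind="stable")
    ps = p[order]
    ranks = np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate((pi0 * m * ps / ranks)[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def correlate_seed_genes(
    expression: dict[str, FeatureMatrix],
    proteins: FeatureMatrix,
    protein_to_gene: dict[str, str],
    alpha: float = 0.05,
    fdr_scope: str = "pooled",
) -> pd.DataFrame:
    """Per-(tissue, gene, protein) Spearman records with q-values.

    Only matched transcript-protein pairs are tested (the protein against
    its own coding gene, tissue by tissue). ``fdr_scope`` is ``pooled``
    (one q-value family across tissues, default) or ``per_tissue``.
    Proteins whose transcript is expressed in no tissue are excluded and
    counted in the log. Sample sets may differ across tissues; each
    tissue is matched to the protein matrix separately.
    """
    if fdr_scope not in {"pooled", "per_tissue"}:
        raise ValueError(f"unknown fdr_scope {fdr_scope!r}")
    rows = []
    seen_genes: set[str] = set()
    for tissue, expr in expression.items():
        shared = expr.index.intersection(proteins.index).sort_values()
        if len(shared) < 4:
            continue
        ex = expr.loc[shared]
        pr = proteins.loc[shared]
        testable = [(p_id, g) for p_id, g in protein_to_gene.items()
                    if g in ex.columns and p_id in pr.columns]
        if not testable:
            continue
        genes = [g for _, g in testable]
        prot_ids = [p for p, _ in testable]
        seen_genes.update(genes)
        # pairwise (matched) correlations only: diagonal of the grid
        rho, pval = spearman_grid(ex.loc[:, genes], pr.loc[:, prot_ids])
        diag_rho = np.diag(rho.to_numpy())
        diag_p = np.diag(pval.to_numpy())
        for (p_id, g), r, pv in zip(testable, diag_rho, diag_p):
            if np.isnan(r):
                continue
            rows.append({"predictor_id": g, "predictor_class": "seed_gene",
                         "tissue": tissue, "protein_id": p_id,
                         "rho": float(r), "p": float(pv), "n": len(shared)})
    out = pd.DataFrame(rows, columns=["predictor_id", "predictor_class",
                                      "tissue", "protein_id", "rho", "p", "n"])
    missing = len(set(protein_to_gene.values()) - seen_genes)
    if missing:
        logger.info("correlate_seed_genes: %d proteins lack an expressed "
                    "transcript in every tissue", missing)
    if out.empty:
        out["q"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
        return out
    if fdr_scope == "pooled":
        out["q"] = qvalues(out["p"].to_numpy())
    else:
        out["q"] = np.nan
        for _, idx in out.groupby("tissue").groups.items():
            out.loc[idx, "q"] = qvalues(out.loc[idx, "p"].to_numpy())
    out["significant"] = out["q"] <= alpha
    return out


def qq_compare(p_a, p_b, labels: tuple[str, str] = ("a", "b")) -> pd.DataFrame:
    """Paired expected/observed -log10 p tables for QQ plotting.

    For each vector the sorted observed -log10 p is set against the
    -log10 uniform order-statistic expectations -log10((i - 0.5)/m).
    Returns a long table with columns group, expected, observed.
    """
    frames = []
    for label, p in zip(labels, (p_a, p_b)):
        p = np.sort(np.asarray(p, float))
        m = len(p)
        if m == 0:
            raise ValueError("empty p-value vector")
        expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)[::-1]
        observed = -np.log10(np.clip(p, np.finfo(float).tiny, 1.0))[::-1]
        frames.append(pd.DataFrame({"group": label, "expected": expected,
                                    "observed": observed}))
    return pd.concat(frames, ignore_index=True)


class MultivariateFit:
    """Joint cross-tissue fit of one protein on its transcript per tissue."""

    def __init__(self, protein_id: str, coefficients: pd.DataFrame,
                 intercept: float, n: int, resid_sd: float):
        self.protein_id = protein_id
        self.coefficients = coefficients  # index tissue; beta, se, tstat, p
        self.intercept = intercept
        self.n = n
        self.resid_sd = resid_sd


def multivariate_seed_model(
    protein: pd.Series,
    expression_by_tissue: dict[str, pd.Series],
) -> MultivariateFit:
    """OLS of a protein on its transcript across all expressing tissues.

    Samples are restricted to those present in the protein series and in
    every tissue series. Collinear tissue columns are dropped with a
    warning before fitting. Returns per-tissue coefficients with t-test
    p-values (q-values are assigned across proteins by the caller, as one
    family over all protein x tissue coefficients).
    """
    import statsmodels.api as sm

    if not expression_by_tissue:
        raise ValueError("protein transcript expressed in no tissue")
    shared = protein.index
    for s in expression_by_tissue.values():
        shared = shared.intersection(s.index)
    shared = shared.sort_values()
    tissues = sorted(expression_by_tissue)
    if len(shared) < len(tissues) + 2:
        raise ValueError("too few common samples for the joint fit")

    X = pd.DataFrame({t: expression_by_tissue[t].loc[shared] for t in tissues})
    design = np.column_stack([np.ones(len(shared)), X.to_numpy(float)])
    while np.linalg.matrix_rank(design) < design.shape[1] and len(tissues) > 1:
        logger.warning("multivariate_seed_model(%s): dropping collinear %s",
                       protein.name, tissues[-1])
        tissues = tissues[:-1]
        X = X.loc[:, tissues]
        design = np.column_stack([np.ones(len(shared)), X.to_numpy(float)])

    y = protein.loc[shared].to_numpy(float)
    fit = sm.OLS(y, design).fit()
    coeffs = pd.DataFrame({
        "beta": fit.params[1:], "se": fit.bse[1:],
        "tstat": fit.tvalues[1:], "p": fit.pvalues[1:],
    }, index=pd.Index(tissues, name="tissue"))
    return MultivariateFit(str(protein.name), coeffs, float(fit.params[0]),
                           int(len(shared)), float(np.sqrt(fit.scale)))


def multivariate_seed_table(
    expression: dict[str, FeatureMatrix],
    proteins: FeatureMatrix,
    protein_to_gene: dict[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fit every protein's cross-tissue model; q-values over all
    protein x tissue coefficients as one family.

    Samples are first restricted to those present in all datasets, as the
    joint model requires a common cohort. Proteins without an expressed
    transcript anywhere are excluded and counted.
    """
    shared = proteins.index
    for expr in expression.values():
        shared = shared.intersection(expr.index)
    shared = shared.sort_values()
    if len(shared) == 0:
        raise ValueError("no samples common to all datasets")

    rows = []
    excluded = 0
    for p_id, gene in protein_to_gene.items():
        if p_id not in proteins.columns:
            continue
        per_tissue = {t: expr.loc[shared, gene]
                      for t, expr in expression.items() if gene in expr.columns}
        if not per_tissue:
            excluded += 1
            continue
        fit = multivariate_seed_model(proteins.loc[shared, p_id], per_tissue)
        for tissue, row in fit.coefficients.iterrows():
            rows.append({"protein_id": p_id, "gene_id": gene, "tissue": tissue,
                         "beta": row["beta"], "se": row["se"], "p": row["p"],
                         "n": fit.n})
    if excluded:
        logger.info("multivariate_seed_table: %d proteins excluded "
                    "(no expressed transcript)", excluded)
    out = pd.DataFrame(rows, columns=["protein_id", "gene_id", "tissue",
                                      "beta", "se", "p", "n"])
    if not out.empty:
        out["q"] = qvalues(out["p"].to_numpy())
        out["significant"] = out["q"] <= alpha
    return out
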
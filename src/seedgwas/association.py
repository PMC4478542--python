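"""Mixed-linear-model association scan with kinship random effects and PCA
covariates, plus marker-based kinship and phenotypic-variance-explained
summaries.

The model for each marker is

    y = mu + PCs * alpha + snp * beta + u + e,   u ~ N(0, K sigma_g^2),
                                                 e ~ N(0, I sigma_e^2),

with K the VanRaden marker-based kinship. Variance components are estimated
by REML through the spectral decomposition of K under the null (no-marker)
model and, by default, reused for every marker ("population parameters
previously determined"); each marker then gets a generalized-least-squares
Wald test of beta = 0. Optional compression replaces individuals by
kinship-clustered groups (average linkage), shrinking the random-effect
dimension as in compressed MLM; compression with as many groups as
individuals reproduces the uncompressed scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import squareform

from .io import MISSING, AssociationResult, GenotypeMatrix, PhenotypeTable
from .structure import StructureResult

logger = logging.getLogger("seedgwas")


@dataclass
class KinshipMatrix:
    accession_ids: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.accession_ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship dimensions do not match accession ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship must be symmetric")


@dataclass
class MlmConfig:
    n_pcs_fixed: int = 2
    compression_groups: Union[int, str, None] = None  # int, "auto", or None/"none"
    variance_component_mode: str = "null_model_once"  # or "per_marker"
    maf_min: float = 0.05
    missing_max: float = 0.2

    def __post_init__(self):
        if self.n_pcs_fixed < 0:
            raise ValueError("n_pcs_fixed must be >= 0")
        if not 0 <= self.maf_min < 0.5:
            raise ValueError("maf_min must lie in [0, 0.5)")
        if self.variance_component_mode not in ("null_model_once", "per_marker"):
            raise ValueError("unknown variance_component_mode")


@dataclass
class PveReport:
    trait_name: str
    snp_ids: list
    r_squared: float
    n_effective_snps: int
    n_observations: int


def kinship_matrix(gm: GenotypeMatrix) -> KinshipMatrix:
    """VanRaden marker-based kinship: centered genotype cross-product scaled
    by sum(2 * maf * (1 - maf)); missing calls mean-imputed."""
    if gm.n_accessions < 2:
        raise ValueError("kinship needs >= 2 accessions")
    X = gm.counts.astype(float)
    X[X == MISSING] = np.nan
    all_missing = np.all(np.isnan(X), axis=0)
    if all_missing.any():
        logger.warning("kinship: dropping %d all-missing SNPs", int(all_missing.sum()))
        X = X[:, ~all_missing]
    mean = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), mean, X)
    p = mean / 2.0
    W = X - mean
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    if denom <= 0:
        raise ValueError("all SNPs monomorphic; kinship undefined")
    K = (W @ W.T) / denom
    K = (K + K.T) / 2.0
    return KinshipMatrix(list(gm.accession_ids), K)


def _ensure_psd(G: np.ndarray) -> np.ndarray:
    """Shrink toward the diagonal until the smallest eigenvalue is ~>= 0."""
    w = np.linalg.eigvalsh(G)
    if w[0] >= -1e-8:
        return G
    s = 0.0
    D = np.diag(np.diag(G))
    while w[0] < -1e-8 and s < 1.0:
        s = min(1.0, (s + 0.05) * 1.2)
        G2 = (1 - s) * G + s * D
        w = np.linalg.eigvalsh(G2)
    logger.warning("kinship not PSD; shrunk toward diagonal with weight %.3f", s)
    return (1 - s) * G + s * D


def _reml_neg_loglik(log_gamma: float, lam: np.ndarray, yr: np.ndarray,
                     Xr: np.ndarray) -> float:
    gamma = np.exp(log_gamma)
    v = gamma * lam + 1.0
    w = 1.0 / v
    Xw = Xr * w[:, None]
    XtVX = Xr.T @ Xw
    try:
        beta = np.linalg.solve(XtVX, Xw.T @ yr)
    except np.linalg.LinAlgError:
        return np.inf
    r = yr - Xr @ beta
    n, p = Xr.shape
    rss = float(r @ (w * r))
    if rss <= 0:
        return np.inf
    sigma_e2 = rss / (n - p)
    sign, logdet_xvx = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return np.inf
    return 0.5 * ((n - p) * np.log(sigma_e2) + np.sum(np.log(v)) + logdet_xvx)


def _estimate_gamma(lam, yr, Xr) -> float:
    """REML estimate of gamma = sigma_g^2 / sigma_e^2: log-scale grid with a
    bounded polish, checking the gamma -> 0 boundary."""
    grid = np.linspace(-12.0, 12.0, 49)
    vals = [_reml_neg_loglik(g, lam, yr, Xr) for g in grid]
    j = int(np.argmin(vals))
    lo, hi = grid[max(0, j - 1)], grid[min(len(grid) - 1, j + 1)]
    res = minimize_scalar(_reml_neg_loglik, bounds=(lo, hi), args=(lam, yr, Xr),
                          method="bounded")
    candidates = [(vals[j], grid[j]), (float(res.fun), float(res.x)),
                  (_reml_neg_loglik(-30.0, lam, yr, Xr), -30.0)]
    _, log_gamma = min(candidates, key=lambda t: t[0])
    return 0.0 if log_gamma <= -29.0 else float(np.exp(log_gamma))


def _compression_structure(K: np.ndarray, n_groups: int):
    """Group individuals by average-linkage clustering of kinship distance and
    return the effective covariance Z K_group Z' plus the group assignment."""
    n = K.shape[0]
    n_groups = max(1, min(n, int(n_groups)))
    if n_groups == n:
        return K, np.arange(n)
    diag = np.diag(K)
    D = diag[:, None] + diag[None, :] - 2 * K
    np.fill_diagonal(D, 0.0)
    D = np.maximum(D, 0.0)
    Zl = linkage(squareform(D, checks=False), method="average")
    groups = fcluster(Zl, t=n_groups, criterion="maxclust") - 1
    g = groups.max() + 1
    M = np.zeros((n, g))
    M[np.arange(n), groups] = 1.0
    sizes = M.sum(axis=0)
    Kg = (M.T @ K @ M) / np.outer(sizes, sizes)
    G = M @ Kg @ M.T
    return (G + G.T) / 2.0, groups


def mlm_scan(gm: GenotypeMatrix, phenotypes: PhenotypeTable, kinship: KinshipMatrix,
             structure: Optional[StructureResult], cfg: MlmConfig,
             trait_name: str, environment: Optional[str] = None) -> AssociationResult:
    """Single-marker mixed-model scan of one trait.

    SNPs failing the MAF or missingness filters are excluded from the output.
    Markers collinear with the fixed effects are reported with a missing
    p-value. Returns per-SNP effect estimates and Wald p-values.
    """
    y_all = phenotypes.values_for(trait_name, environment).dropna()
    shared = [a for a in gm.accession_ids if a in set(y_all.index) and a in set(kinship.accession_ids)]
    if len(shared) < 30:
        raise ValueError(f"trait {trait_name!r} present for only {len(shared)} accessions")
    acc_idx = {a: i for i, a in enumerate(gm.accession_ids)}
    rows = np.array([acc_idx[a] for a in shared])
    kin_idx = {a: i for i, a in enumerate(kinship.accession_ids)}
    krows = np.array([kin_idx[a] for a in shared])
    y = y_all.reindex(shared).to_numpy(dtype=float)
    n = len(shared)

    # fixed effects: intercept + leading PCs
    X = np.ones((n, 1))
    if cfg.n_pcs_fixed > 0:
        if structure is None:
            raise ValueError("n_pcs_fixed > 0 requires a StructureResult")
        s_idx = {a: i for i, a in enumerate(structure.accession_ids)}
        srows = np.array([s_idx[a] for a in shared])
        X = np.column_stack([X, structure.pc_scores[srows, :cfg.n_pcs_fixed]])

    # SNP filters
    sub = gm.counts[rows]
    called = sub != MISSING
    n_called = called.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(called, sub, 0).sum(axis=0) / np.maximum(2 * n_called, 1)
    maf = np.minimum(freq, 1 - freq)
    miss_frac = 1.0 - n_called / n
    keep = (maf >= cfg.maf_min) & (miss_frac <= cfg.missing_max) & (n_called > 0)
    snp_cols = np.where(keep)[0]

    G = kinship.values[np.ix_(krows, krows)]
    descriptor = f"MLM(K=VanRaden, PCs={cfg.n_pcs_fixed}"
    groups = None
    if cfg.compression_groups not in (None, "none"):
        if cfg.compression_groups == "auto":
            G, groups, n_grp = _auto_compression(G, y, X)
            descriptor += f", compression=auto->{n_grp}"
        else:
            G, groups = _compression_structure(G, int(cfg.compression_groups))
            descriptor += f", compression={int(cfg.compression_groups)}"
    descriptor += f", vc={cfg.variance_component_mode})"
    G = _ensure_psd(G)
    lam, U = np.linalg.eigh(G)
    lam = np.maximum(lam, 0.0)

    yr = U.T @ y
    Xr = U.T @ X
    gamma = _estimate_gamma(lam, yr, Xr)
    logger.info("null-model REML: gamma=sigma_g2/sigma_e2=%.4g", gamma)

    geno = sub[:, snp_cols].astype(float)
    geno[geno == MISSING * 1.0] = np.nan
    col_mean = np.nanmean(geno, axis=0)
    geno = np.where(np.isnan(geno), col_mean, geno)
    Gr = U.T @ geno

    if cfg.variance_component_mode == "per_marker":
        betas, pvals = _scan_per_marker(lam, yr, Xr, Gr)
    else:
        betas, pvals = _scan_fixed_gamma(gamma, lam, yr, Xr, Gr)

    df = pd.DataFrame({
        "snp_id": [gm.snp_ids[j] for j in snp_cols],
        "chrom": gm.chrom[snp_cols],
        "pos_bp": gm.pos_bp[snp_cols],
        "effect": betas,
        "p_value": pvals,
    })
    return AssociationResult(trait_name=trait_name, df=df, model_descriptor=descriptor)


def _scan_fixed_gamma(gamma, lam, yr, Xr, Gr):
    n, p = Xr.shape
    v = gamma * lam + 1.0
    sw = 1.0 / np.sqrt(v)
    Xw = Xr * sw[:, None]
    yw = yr * sw
    Gw = Gr * sw[:, None]
    Q, _ = np.linalg.qr(Xw)
    y_res = yw - Q @ (Q.T @ yw)
    G_res = Gw - Q @ (Q.T @ Gw)
    gss = np.einsum("ij,ij->j", G_res, G_res)
    gty = G_res.T @ y_res
    rss0 = float(y_res @ y_res)
    dof = n - p - 1
    ok = gss > 1e-10 * np.maximum(1.0, np.einsum("ij,ij->j", Gw, Gw))
    beta = np.full(Gr.shape[1], np.nan)
    pval = np.full(Gr.shape[1], np.nan)
    beta[ok] = gty[ok] / gss[ok]
    rss = rss0 - beta[ok] ** 2 * gss[ok]
    rss = np.maximum(rss, 1e-300)
    se2 = rss / dof / gss[ok]
    tstat = beta[ok] / np.sqrt(se2)
    pval[ok] = 2.0 * stats.t.sf(np.abs(tstat), dof)
    pval[ok] = np.clip(pval[ok], np.finfo(float).tiny, 1.0)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("%d markers collinear with fixed effects; p set missing", n_bad)
    return beta, pval


def _scan_per_marker(lam, yr, Xr, Gr):
    m = Gr.shape[1]
    beta = np.full(m, np.nan)
    pval = np.full(m, np.nan)
    for j in range(m):
        Xj = np.column_stack([Xr, Gr[:, j]])
        if np.linalg.matrix_rank(Xj) < Xj.shape[1]:
            continue
        gamma = _estimate_gamma(lam, yr, Xj)
        b, p = _scan_fixed_gamma(gamma, lam, yr, Xr, Gr[:, j:j + 1])
        beta[j], pval[j] = b[0], p[0]
    return beta, pval


def _auto_compression(K, y, X):
    """Scan group counts {1, 2, 4, ..., n}; keep the null-REML maximizer."""
    n = K.shape[0]
    counts = []
    c = 1
    while c < n:
        counts.append(c)
        c *= 2
    counts.append(n)
    best = None
    for g in counts:
        G, groups = _compression_structure(K, g)
        lam, U = np.linalg.eigh(_ensure_psd(G))
        lam = np.maximum(lam, 0.0)
        yr, Xr = U.T @ y, U.T @ X
        gamma = _estimate_gamma(lam, yr, Xr)
        nll = _reml_neg_loglik(np.log(max(gamma, 1e-30)), lam, yr, Xr)
        if best is None or nll < best[0]:
            best = (nll, G, groups, g)
    _, G, groups, g = best
    return G, groups, g


def ols_scan(gm: GenotypeMatrix, phenotypes: PhenotypeTable, trait_name: str,
             environment: Optional[str] = None, maf_min: float = 0.05,
             missing_max: float = 0.2) -> AssociationResult:
    """Naive single-marker regression with no structure control; the baseline
    the mixed model is judged against."""
    identity = KinshipMatrix(list(gm.accession_ids), np.eye(gm.n_accessions))
    cfg = MlmConfig(n_pcs_fixed=0, maf_min=maf_min, missing_max=missing_max)
    res = mlm_scan(gm, phenotypes, identity, None, cfg, trait_name, environment)
    res.model_descriptor = "OLS(no structure control)"
    return res


def pve_of_snps(gm: GenotypeMatrix, phenotypes: PhenotypeTable,
                snp_ids: Sequence[str], trait_name: str,
                environment: Optional[str] = None) -> PveReport:
    """Joint OLS R-squared of the trait on the listed SNP allele counts.

    Collinear SNP columns are dropped (the effective count is reported).
    """
    y_all = phenotypes.values_for(trait_name, environment).dropna()
    shared = [a for a in gm.accession_ids if a in set(y_all.index)]
    cols = [gm.snp_index(s) for s in snp_ids]
    if len(shared) < len(cols) + 2:
        raise ValueError("need at least |snp_ids| + 2 complete observations")
    rows = np.array([gm.accession_ids.index(a) for a in shared])
    y = y_all.reindex(shared).to_numpy(dtype=float)
    X = gm.counts[np.ix_(rows, cols)].astype(float)
    X[X == MISSING] = np.nan
    X = np.where(np.isnan(X), np.nanmean(X, axis=0), X)
    Xc = X - X.mean(axis=0)
    rank = np.linalg.matrix_rank(Xc) if Xc.size else 0
    if rank < Xc.shape[1]:
        logger.warning("pve_of_snps: %d of %d SNP columns collinear",
                       Xc.shape[1] - rank, Xc.shape[1])
    yc = y - y.mean()
    tss = float(yc @ yc)
    if tss == 0:
        return PveReport(trait_name, list(snp_ids), 0.0, rank, len(y))
    coef, rss_arr, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    resid = yc - Xc @ coef
    r2 = 1.0 - float(resid @ resid) / tss
    return PveReport(trait_name, list(snp_ids), max(0.0, min(1.0, r2)), rank, len(y))
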
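"""Linkage disequilibrium: pairwise r², regional matrices, decay extent, and
multiple-testing thresholds.

r² here is the composite (genotype-correlation) measure: the squared Pearson
correlation of minor-allele count vectors over accessions with calls at both
SNPs. For highly inbred, unphased material this coincides closely with the
haplotype r² and needs no phasing.

Two significance thresholds are provided: the plain Bonferroni cutoff
``alpha / n_tests`` and an LD-bin correction in which the effective number of
independent tests is ``genome_size_bp / ld_extent_bp`` — the number of LD
"bins" the genome decomposes into given the average distance at which r²
decays to background.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .io import MISSING, GenotypeMatrix

logger = logging.getLogger("seedgwas")


@dataclass
class LdMatrix:
    chrom: str
    snp_ids: list            # ordered by position
    pos_bp: np.ndarray
    r2: np.ndarray           # symmetric, diagonal 1 for polymorphic SNPs


@dataclass
class LdDecayEstimate:
    bin_edges_bp: np.ndarray      # len nbins + 1
    mean_r2_per_bin: np.ndarray
    n_pairs_per_bin: np.ndarray
    background_r2: float
    extent_bp: Optional[float]    # None when censored (never drops below background)

    @property
    def censored(self) -> bool:
        return self.extent_bp is None

    def __str__(self):
        if self.censored:
            return f"LD extent > {int(self.bin_edges_bp[-1])} bp (censored)"
        return f"LD extent = {int(self.extent_bp)} bp (r2 < {self.background_r2})"


@dataclass
class ThresholdConfig:
    alpha: float = 0.05
    n_tests: int = 265_487
    genome_size_bp: float = 730e6
    ld_extent_bp: float = 150e3

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0,1)")
        if self.n_tests < 1 or self.genome_size_bp <= 0 or self.ld_extent_bp <= 0:
            raise ValueError("counts and lengths must be positive")


def _complete_pair_columns(gm: GenotypeMatrix, i: int, j: int):
    a = gm.counts[:, i].astype(float)
    b = gm.counts[:, j].astype(float)
    ok = (a != MISSING) & (b != MISSING)
    return a[ok], b[ok]


def pairwise_r2(gm: GenotypeMatrix, snp_a: str, snp_b: str) -> float:
    """Composite r² between two SNPs; NaN if either is monomorphic on the
    shared non-missing accessions."""
    i, j = gm.snp_index(snp_a), gm.snp_index(snp_b)
    a, b = _complete_pair_columns(gm, i, j)
    return _r2_vectors(a, b)


def _r2_vectors(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(min(r * r, 1.0))


def regional_ld_matrix(gm: GenotypeMatrix, chrom: str, start_bp: int,
                       end_bp: int) -> LdMatrix:
    """Full symmetric r² matrix for the SNPs inside [start_bp, end_bp]."""
    idx = gm.snps_in_region(chrom, start_bp, end_bp)
    if len(idx) == 0:
        logger.warning("regional_ld_matrix: empty region %s:%d-%d", chrom, start_bp, end_bp)
        return LdMatrix(chrom, [], np.array([], dtype=np.int64), np.zeros((0, 0)))
    X = gm.counts[:, idx].astype(float)
    X[X == MISSING] = np.nan
    m = len(idx)
    r2 = np.empty((m, m))
    if not np.isnan(X).any():
        sd = X.std(axis=0)
        poly = sd > 0
        Z = np.zeros_like(X)
        Z[:, poly] = (X[:, poly] - X[:, poly].mean(axis=0)) / sd[poly]
        C = (Z.T @ Z) / X.shape[0]
        r2 = np.clip(C * C, 0.0, 1.0)
        r2[~poly, :] = np.nan
        r2[:, ~poly] = np.nan
        np.fill_diagonal(r2, np.where(poly, 1.0, np.nan))
    else:
        for u in range(m):
            r2[u, u] = 1.0 if np.nanstd(X[:, u]) > 0 else np.nan
            for v in range(u + 1, m):
                ok = ~np.isnan(X[:, u]) & ~np.isnan(X[:, v])
                val = _r2_vectors(X[ok, u], X[ok, v])
                r2[u, v] = r2[v, u] = val
    return LdMatrix(chrom, [gm.snp_ids[k] for k in idx], gm.pos_bp[idx], r2)


def ld_decay_extent(gm: GenotypeMatrix, max_dist_bp: int = 1_000_000,
                    bin_width_bp: int = 25_000, background_r2: float = 0.1,
                    max_pairs: int = 200_000, rng_seed: int = 0,
                    summary: str = "mean") -> LdDecayEstimate:
    """Mean r² in distance bins over sampled intra-chromosomal SNP pairs.

    The decay extent is the upper edge of the first bin whose summary r²
    drops below ``background_r2``; if no bin does within ``max_dist_bp`` the
    estimate is censored (``extent_bp`` is None).
    """
    rng = np.random.default_rng(rng_seed)
    pair_i, pair_j = [], []
    for chrom in dict.fromkeys(gm.chrom):
        idx = np.where(gm.chrom == chrom)[0]
        if len(idx) < 2:
            continue
        pos = gm.pos_bp[idx]
        hi = np.searchsorted(pos, pos + max_dist_bp, side="right")
        span = hi - np.arange(len(idx)) - 1  # partners within range, to the right
        total = int(span.sum())
        if total == 0:
            continue
        take = min(total, max(1, int(max_pairs * len(idx) / gm.n_snps)))
        cum = np.concatenate([[0], np.cumsum(span)])
        draws = rng.integers(0, total, size=take)
        left = np.searchsorted(cum, draws, side="right") - 1
        right = left + 1 + (draws - cum[left])
        pair_i.append(idx[left])
        pair_j.append(idx[right])
    if not pair_i:
        raise ValueError("no intra-chromosomal SNP pairs within max_dist_bp")
    pi = np.concatenate(pair_i)
    pj = np.concatenate(pair_j)
    if len(pi) < 1000:
        logger.warning("ld_decay_extent: only %d pairs available", len(pi))
    dist = np.abs(gm.pos_bp[pj] - gm.pos_bp[pi]).astype(float)

    A = gm.counts[:, pi].astype(float)
    B = gm.counts[:, pj].astype(float)
    A[A == MISSING] = np.nan
    B[B == MISSING] = np.nan
    ok = ~np.isnan(A) & ~np.isnan(B)
    A = np.where(ok, A, np.nan)
    B = np.where(ok, B, np.nan)
    n = ok.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ma = np.nansum(A, axis=0) / n
        mb = np.nansum(B, axis=0) / n
        cov = np.nansum((A - ma) * (B - mb), axis=0)
        va = np.nansum((A - ma) ** 2, axis=0)
        vb = np.nansum((B - mb) ** 2, axis=0)
        r2 = np.where((va > 0) & (vb > 0), (cov * cov) / (va * vb), np.nan)

    nbins = int(math.ceil(max_dist_bp / bin_width_bp))
    edges = np.arange(nbins + 1) * bin_width_bp
    which = np.minimum((dist / bin_width_bp).astype(int), nbins - 1)
    mean_r2 = np.full(nbins, np.nan)
    npairs = np.zeros(nbins, dtype=int)
    for b in range(nbins):
        sel = (which == b) & ~np.isnan(r2)
        npairs[b] = sel.sum()
        if npairs[b]:
            mean_r2[b] = np.median(r2[sel]) if summary == "median" else r2[sel].mean()

    extent = None
    for b in range(nbins):
        if npairs[b] and mean_r2[b] < background_r2:
            extent = float(edges[b + 1])
            break
    return LdDecayEstimate(edges, mean_r2, npairs, background_r2, extent)


def bonferroni_cutoff(cfg: ThresholdConfig) -> float:
    """Experiment-wise alpha split over the raw number of tests."""
    return cfg.alpha / cfg.n_tests


def ldbin_cutoff(cfg: ThresholdConfig) -> float:
    """alpha divided by the effective test count genome_size / LD extent.

    The effective count is kept real-valued before dividing.
    """
    if cfg.genome_size_bp < cfg.ld_extent_bp:
        raise ValueError("genome size must be >= LD extent")
    effective_tests = cfg.genome_size_bp / cfg.ld_extent_bp
    return cfg.alpha / effective_tests


def nearest_power_of_ten(x: float) -> float:
    """The power of ten nearest to x on a log scale (e.g. 1.03e-5 -> 1e-5)."""
    if x <= 0:
        raise ValueError("x must be positive")
    return 10.0 ** round(math.log10(x))
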
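"""Population structure and trait-level statistics.

PCA on standardized genotypes (each SNP centered and divided by the expected
binomial SD sqrt(2*maf*(1-maf))), K-means grouping on the leading components,
group-wise Welch t-tests of trait differentiation, per-group allele
frequencies, pairwise trait correlations with regression slopes, and
across-environment repeatability (broad-sense heritability) from a one-way
random-effects ANOVA on accession.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING, GenotypeMatrix, PhenotypeTable

logger = logging.getLogger("seedgwas")

SIGNIFICANCE_THRESHOLD = 1e-4  # group differentiation flag


@dataclass
class StructureResult:
    accession_ids: list
    pc_scores: np.ndarray          # accessions x n_pcs
    variance_explained: np.ndarray  # fraction per PC, non-increasing
    group_labels: Optional[np.ndarray] = None  # 1..k per accession


@dataclass
class GroupDifferentiation:
    trait_name: str
    groups: list
    p_values: Dict[Tuple[int, int], float]   # unordered group pairs
    significant: Dict[Tuple[int, int], bool]

    def p(self, g1: int, g2: int) -> float:
        return self.p_values[tuple(sorted((g1, g2)))]


@dataclass
class TraitCorrelation:
    trait_x: str
    trait_y: str
    pearson_r: float
    ols_slope_beta: float
    n_pairs: int


@dataclass
class HeritabilityEstimate:
    trait_name: str
    n_environments: int
    repeatability_H: float
    var_accession: float
    var_residual: float


def _imputed_standardized(gm: GenotypeMatrix):
    """Mean-imputed genotype matrix standardized per SNP; constant SNPs dropped."""
    X = gm.counts.astype(float)
    X[X == MISSING] = np.nan
    mean = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), mean, X)
    maf = gm.compute_maf()
    sd = np.sqrt(2.0 * maf * (1.0 - maf))
    keep = (sd > 0) & (X.std(axis=0) > 0)
    if (~keep).sum():
        logger.warning("dropping %d constant SNPs before PCA", int((~keep).sum()))
    return (X[:, keep] - mean[keep]) / sd[keep], keep


def compute_pca(gm: GenotypeMatrix, n_pcs: int = 2) -> StructureResult:
    """Genotype PCA; scores have a fixed sign convention (each component's
    largest-magnitude SNP loading is positive)."""
    if gm.n_accessions < 2:
        raise ValueError("PCA needs at least 2 accessions")
    Z, _ = _imputed_standardized(gm)
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if len(s) else 0
    if n_pcs > rank:
        raise ValueError(f"n_pcs={n_pcs} exceeds rank {rank}")
    scores = U[:, :n_pcs] * s[:n_pcs]
    for j in range(n_pcs):
        lead = np.argmax(np.abs(Vt[j]))
        if Vt[j, lead] < 0:
            scores[:, j] = -scores[:, j]
    var = (s ** 2) / np.sum(s ** 2)
    return StructureResult(list(gm.accession_ids), scores, var[:n_pcs])


def kmeans_groups(scores: np.ndarray, k: int = 3, n_restarts: int = 10,
                  rng_seed: int = 0) -> np.ndarray:
    """Best-of-restarts K-means labels in {1..k}, deterministic given the seed.

    Cluster indices are relabelled by ascending centroid on the first score
    axis so labels do not depend on initialisation order.
    """
    from sklearn.cluster import KMeans

    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return np.ones(len(scores), dtype=int)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=rng_seed)
    raw = km.fit_predict(scores)
    order = np.argsort(km.cluster_centers_[:, 0], kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    return relabel[raw]


def group_trait_ttests(phenotypes: PhenotypeTable, labels: Sequence[int],
                       accession_ids: Sequence, trait_name: str,
                       environment: Optional[str] = None,
                       welch: bool = True) -> GroupDifferentiation:
    """Two-sided Welch t-test of the trait between every pair of groups.

    Pairs where either group has fewer than 2 observations get a missing
    (NaN) p-value. Two groups with identical constant values are reported as
    p = 1 (no evidence of differentiation) rather than undefined.
    """
    values = phenotypes.values_for(trait_name, environment)
    lab = pd.Series(np.asarray(labels), index=list(accession_ids))
    groups = sorted(set(lab))
    pvals, flags = {}, {}
    for g1, g2 in combinations(groups, 2):
        x = values.reindex(lab.index[lab == g1]).dropna().to_numpy()
        y = values.reindex(lab.index[lab == g2]).dropna().to_numpy()
        if len(x) < 2 or len(y) < 2:
            p = float("nan")
        elif x.std() == 0 and y.std() == 0:
            p = 1.0 if x.mean() == y.mean() else 0.0
        else:
            p = float(stats.ttest_ind(x, y, equal_var=not welch).pvalue)
        pvals[(g1, g2)] = p
        flags[(g1, g2)] = bool(p <= SIGNIFICANCE_THRESHOLD) if np.isfinite(p) else False
    return GroupDifferentiation(trait_name, groups, pvals, flags)


def allele_freq_by_group(gm: GenotypeMatrix, labels: Sequence[int],
                         snp_id: str) -> Dict[int, float]:
    """Minor-allele frequency of one SNP within each group; NaN where a group
    has no called genotypes."""
    col = gm.column(snp_id)
    lab = np.asarray(labels)
    out = {}
    for g in sorted(set(lab)):
        sub = col[lab == g]
        called = sub[sub != MISSING]
        out[g] = float(called.sum() / (2 * len(called))) if len(called) else float("nan")
    return out


def trait_correlation(phenotypes: PhenotypeTable, trait_x: str, trait_y: str,
                      env_x: Optional[str] = None,
                      env_y: Optional[str] = None) -> TraitCorrelation:
    """Pearson r and least-squares slope of y on x over complete pairs."""
    x = phenotypes.values_for(trait_x, env_x)
    y = phenotypes.values_for(trait_y, env_y)
    common = x.index.intersection(y.index)
    xv = x.reindex(common).to_numpy(dtype=float)
    yv = y.reindex(common).to_numpy(dtype=float)
    ok = ~np.isnan(xv) & ~np.isnan(yv)
    xv, yv = xv[ok], yv[ok]
    if len(xv) < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(xv) == 0:
        return TraitCorrelation(trait_x, trait_y, float("nan"), float("nan"), len(xv))
    r = float(stats.pearsonr(xv, yv).statistic)
    beta = float(np.polyfit(xv, yv, 1)[0])
    return TraitCorrelation(trait_x, trait_y, r, beta, len(xv))


def repeatability_across_environments(phenotypes: PhenotypeTable, trait_base: str,
                                      environments: Optional[Sequence[str]] = None
                                      ) -> HeritabilityEstimate:
    """Broad-sense repeatability H from a one-way random-effects ANOVA on
    accession over environments.

    H = Var(accession) / (Var(accession) + Var(residual)); the among-accession
    component uses the unequal-n coefficient k0 = (N - sum n_i^2 / N)/(a - 1),
    and negative variance components are clamped to zero (so H is in [0, 1]).
    """
    if environments is None:
        environments = phenotypes.environments_for(trait_base)
    environments = [str(e) for e in environments]
    if len(environments) < 2:
        raise ValueError("repeatability needs >= 2 environments")
    frames = []
    for env in environments:
        v = phenotypes.values_for(trait_base, env).dropna()
        frames.append(pd.DataFrame({"accession_id": v.index, "value": v.values}))
    df = pd.concat(frames, ignore_index=True)
    sizes = df.groupby("accession_id")["value"].count()
    if (sizes >= 2).sum() < 2:
        raise ValueError("need >= 2 accessions measured in >= 2 environments")
    df = df[df["accession_id"].isin(sizes.index)]
    grand = df["value"].mean()
    grp = df.groupby("accession_id")["value"]
    n_i = grp.count().to_numpy(dtype=float)
    means = grp.mean().to_numpy()
    N, a = n_i.sum(), len(n_i)
    ss_among = float((n_i * (means - grand) ** 2).sum())
    ss_within = float(((df["value"] - grp.transform("mean")) ** 2).sum())
    df_among, df_within = a - 1, N - a
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within if df_within > 0 else float("nan")
    k0 = (N - (n_i ** 2).sum() / N) / df_among
    var_acc = max(0.0, (ms_among - ms_within) / k0)
    var_res = max(0.0, ms_within)
    denom = var_acc + var_res
    H = var_acc / denom if denom > 0 else 0.0
    return HeritabilityEstimate(trait_base, len(environments), float(H),
                                var_acc, var_res)
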
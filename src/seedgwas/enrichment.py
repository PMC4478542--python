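"""Exact 2x2 enrichment tests for QTL-GWAS overlap and cross-taxa
correspondence.

The Fisher exact test is computed by direct log-space enumeration of the
hypergeometric support with the table margins fixed: the one-sided
(enrichment) p-value is P(A >= a) and the two-sided p-value sums the
probabilities of all tables no more likely than the observed one
(point-probability method).

Three constructions are provided:

* within-genome: tested SNPs cross-classified by significance and membership
  in merged QTL intervals;
* cross-taxa (gene-based): collinear ortholog pairs on an orthologous
  chromosome pair cross-classified by membership of the A-side gene in an
  association region and of the B-side gene in any merged B-genome QTL
  interval;
* cross-taxa (interval-based): A-genome QTL intervals projected through the
  ortholog map and classified as corresponding (projected span overlaps a
  B interval) or not, compared against the chance coverage of the projected
  gene universe.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .io import AssociationResult, QtlInterval
from .intervals import merge_intervals

logger = logging.getLogger("seedgwas")


@dataclass
class ContingencyTable:
    """Counts (a, b, c, d): a = in both categories, b = in 1 only,
    c = in 2 only, d = in neither."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_tuple(self) -> Tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass
class EnrichmentResult:
    table: ContingencyTable
    p_one_sided: float
    p_two_sided: float
    odds_ratio: float
    degenerate: bool = False
    detail: dict = field(default_factory=dict)


@dataclass
class OrthologPairSet:
    """Collinear ortholog gene pairs linking genomes A and B."""

    df: pd.DataFrame  # gene_a, chrom_a, start_a, end_a, gene_b, chrom_b, start_b, end_b, strand

    COLUMNS = ("gene_a", "chrom_a", "start_a", "end_a",
               "gene_b", "chrom_b", "start_b", "end_b", "strand")

    def __post_init__(self):
        missing = [c for c in self.COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"ortholog table missing columns: {missing}")
        if self.df.duplicated(subset=["gene_a", "gene_b"]).any():
            raise ValueError("duplicate (gene_a, gene_b) pairs")

    def on_chromosome_pair(self, chrom_a: str, chrom_b: str) -> pd.DataFrame:
        df = self.df
        return df[(df["chrom_a"] == chrom_a) & (df["chrom_b"] == chrom_b)]


def read_ortholog_pairs(path) -> OrthologPairSet:
    df = pd.read_csv(path, sep="\t", dtype={"chrom_a": str, "chrom_b": str})
    return OrthologPairSet(df)


def write_ortholog_pairs(pairs: OrthologPairSet, path) -> None:
    pairs.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# exact test


def _log_hypergeom_pmf(support: np.ndarray, r1: int, r2: int, c1: int) -> np.ndarray:
    n = r1 + r2

    def logC(nn, kk):
        return gammaln(nn + 1) - gammaln(kk + 1) - gammaln(nn - kk + 1)

    return logC(r1, support) + logC(r2, c1 - support) - logC(n, c1)


_EXACT_TOTAL_MAX = 50_000  # integer-arithmetic path below this table total


def fisher_exact(table: ContingencyTable, sided: str = "one_greater") -> EnrichmentResult:
    """Exact test of independence for a 2x2 table.

    ``one_greater`` gives the enrichment-direction p-value P(A >= a) under the
    fixed-margin hypergeometric null; ``two`` the point-probability two-sided
    p-value (sum of outcomes no more likely than the observed table). Both are
    always populated on the result. Table probabilities are enumerated over
    the hypergeometric support with exact integer weights for moderate totals,
    and in log space for very large tables where big-integer enumeration is
    impractical.
    """
    if sided not in ("one_greater", "two"):
        raise ValueError("sided must be 'one_greater' or 'two'")
    a, b, c, d = table.as_tuple()
    r1, r2, c1 = a + b, c + d, a + c
    odds = _odds_ratio(a, b, c, d)
    if r1 == 0 or r2 == 0 or c1 == 0 or (b + d) == 0:
        return EnrichmentResult(table, 1.0, 1.0, odds, degenerate=True)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    if table.total <= _EXACT_TOTAL_MAX:
        weights = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)]
        total_w = math.comb(r1 + r2, c1)
        obs_w = weights[a - lo]
        p_one = _ratio(sum(weights[a - lo:]), total_w)
        p_two = _ratio(sum(w for w in weights if w <= obs_w), total_w)
    else:
        support = np.arange(lo, hi + 1)
        logp = _log_hypergeom_pmf(support, r1, r2, c1)
        obs = a - lo
        p_one = float(np.exp(logsumexp(logp[obs:])))
        keep = logp <= logp[obs] + 1e-9  # tolerate fp ties at the observed mass
        p_two = float(np.exp(logsumexp(logp[keep])))
    return EnrichmentResult(table, min(p_one, 1.0), min(p_two, 1.0), odds)


def _ratio(num: int, den: int) -> float:
    """Correctly-rounded float of a big-integer ratio."""
    from fractions import Fraction

    return float(Fraction(num, den))


def _odds_ratio(a, b, c, d) -> float:
    if b * c == 0:
        return float("inf") if a * d > 0 else float("nan")
    return (a * d) / (b * c)


def uniformized_p(table: ContingencyTable, rng: np.random.Generator) -> float:
    """Randomized p-value U = P(A > a) + V * P(A = a), V ~ U(0,1).

    For a discrete exact test the raw p-value is conservative (stochastically
    larger than uniform); this standard transform is exactly U(0,1) under the
    null and is what calibration checks should use.
    """
    a, b, c, d = table.as_tuple()
    r1, r2, c1 = a + b, c + d, a + c
    if r1 == 0 or r2 == 0 or c1 == 0 or (b + d) == 0:
        return float(rng.uniform())
    lo, hi = max(0, c1 - r2), min(r1, c1)
    support = np.arange(lo, hi + 1)
    logp = _log_hypergeom_pmf(support, r1, r2, c1)
    obs = a - lo
    p_gt = float(np.exp(logsumexp(logp[obs + 1:]))) if obs + 1 <= hi - lo else 0.0
    p_eq = float(np.exp(logp[obs]))
    return p_gt + float(rng.uniform()) * p_eq


# ---------------------------------------------------------------------------
# classification helpers


def _point_in_merged(chrom: np.ndarray, pos: np.ndarray,
                     merged: Sequence[QtlInterval]) -> np.ndarray:
    """Boolean mask: position lies inside any merged (disjoint) interval."""
    inside = np.zeros(len(pos), dtype=bool)
    by_chrom = {}
    for iv in merged:
        by_chrom.setdefault(iv.chrom, []).append((iv.start_bp, iv.end_bp))
    for ch, spans in by_chrom.items():
        spans.sort()
        starts = np.array([s for s, _ in spans])
        ends = np.array([e for _, e in spans])
        sel = np.where(chrom == ch)[0]
        if len(sel) == 0:
            continue
        k = np.searchsorted(starts, pos[sel], side="right") - 1
        ok = (k >= 0) & (pos[sel] <= ends[np.maximum(k, 0)])
        inside[sel[ok]] = True
    return inside


def _gene_membership(df: pd.DataFrame, side: str, intervals: Sequence[QtlInterval],
                     rule: str = "midpoint") -> np.ndarray:
    merged = merge_intervals(list(intervals))
    chrom = df[f"chrom_{side}"].to_numpy(dtype=object)
    start = df[f"start_{side}"].to_numpy(dtype=np.int64)
    end = df[f"end_{side}"].to_numpy(dtype=np.int64)
    if rule == "midpoint":
        mid = (start + end) // 2
        return _point_in_merged(chrom, mid, merged)
    if rule == "overlap":
        inside = np.zeros(len(df), dtype=bool)
        for iv in merged:
            inside |= (chrom == iv.chrom) & (start <= iv.end_bp) & (end >= iv.start_bp)
        return inside
    raise ValueError("rule must be 'midpoint' or 'overlap'")


# ---------------------------------------------------------------------------
# the three constructions


def qtl_gwas_overlap_test(assoc: AssociationResult,
                          qtl_intervals: Sequence[QtlInterval],
                          sig_threshold: float = 1e-5) -> EnrichmentResult:
    """Within-genome overlap of association evidence with QTL intervals.

    Every tested SNP is classified by (significant at sig_threshold?, inside
    any merged QTL interval?); the 2x2 table (sig&in, sig&out, nonsig&in,
    nonsig&out) feeds the exact test with enrichment one-sided headline.
    """
    df = assoc.df.dropna(subset=["p_value"])
    merged = merge_intervals(list(qtl_intervals))
    inside = _point_in_merged(df["chrom"].to_numpy(dtype=object),
                              df["pos_bp"].to_numpy(dtype=np.int64), merged)
    sig = (df["p_value"] <= sig_threshold).to_numpy()
    table = ContingencyTable(
        a=int((sig & inside).sum()), b=int((sig & ~inside).sum()),
        c=int((~sig & inside).sum()), d=int((~sig & ~inside).sum()),
    )
    if table.a + table.b == 0:
        logger.warning("qtl_gwas_overlap_test: no significant SNPs at %.3g", sig_threshold)
    res = fisher_exact(table)
    res.detail = {"sig_threshold": sig_threshold, "n_merged_intervals": len(merged)}
    return res


def cross_taxa_correspondence_test(hotspot_region: QtlInterval,
                                   qtl_intervals_b: Sequence[QtlInterval],
                                   orthologs: OrthologPairSet,
                                   chrom_pairing: Tuple[str, str],
                                   membership_rule: str = "midpoint",
                                   flank_bp: int = 0) -> EnrichmentResult:
    """Gene-based correspondence of an A-genome association region with
    B-genome QTL intervals over collinear orthologs on one chromosome pair."""
    chrom_a, chrom_b = chrom_pairing
    universe = orthologs.on_chromosome_pair(chrom_a, chrom_b)
    if universe.empty:
        raise ValueError(f"no collinear orthologs on chromosome pair ({chrom_a}, {chrom_b})")
    region = QtlInterval(chrom=hotspot_region.chrom,
                         start_bp=max(1, hotspot_region.start_bp - flank_bp),
                         end_bp=hotspot_region.end_bp + flank_bp)
    in_a = _gene_membership(universe, "a", [region], membership_rule)
    in_b = _gene_membership(universe, "b", list(qtl_intervals_b), membership_rule)
    table = ContingencyTable(
        a=int((in_a & in_b).sum()), b=int((in_a & ~in_b).sum()),
        c=int((~in_a & in_b).sum()), d=int((~in_a & ~in_b).sum()),
    )
    res = fisher_exact(table)
    res.detail = {"chrom_pairing": chrom_pairing, "n_universe": len(universe)}
    return res


def qtl_qtl_correspondence_test(qtl_a: Sequence[QtlInterval],
                                qtl_b: Sequence[QtlInterval],
                                orthologs: OrthologPairSet,
                                membership_rule: str = "midpoint") -> EnrichmentResult:
    """Interval-based correspondence: each A interval is projected to genome B
    via the ortholog pairs whose A gene it contains (span of their B positions
    on the B chromosome carrying most of them) and called corresponding when
    the projection overlaps a merged B interval. The observed within/outside
    split is compared against the chance coverage of the projected gene
    universe by B intervals."""
    merged_b = merge_intervals(list(qtl_b))
    df = orthologs.df
    mid_b = ((df["start_b"].to_numpy(np.int64) + df["end_b"].to_numpy(np.int64)) // 2)
    within, outside, excluded = 0, 0, 0
    touched_b_chroms = set()
    for iv in qtl_a:
        in_iv = _gene_membership(df, "a", [iv], membership_rule)
        if not in_iv.any():
            excluded += 1
            continue
        sub = df[in_iv]
        bchrom = sub["chrom_b"].mode().iloc[0]
        touched_b_chroms.add(bchrom)
        bpos = mid_b[in_iv.nonzero()[0]][(sub["chrom_b"] == bchrom).to_numpy()]
        proj = QtlInterval(chrom=bchrom, start_bp=int(bpos.min()), end_bp=int(bpos.max()))
        hit = any(iv_b.chrom == proj.chrom and
                  max(proj.start_bp, iv_b.start_bp) <= min(proj.end_bp, iv_b.end_bp)
                  for iv_b in merged_b)
        within, outside = within + hit, outside + (not hit)
    if excluded:
        logger.warning("qtl_qtl_correspondence_test: %d A-intervals without "
                       "ortholog-bearing genes excluded", excluded)
    uni = df[df["chrom_b"].isin(touched_b_chroms)] if touched_b_chroms else df.iloc[:0]
    if len(uni):
        in_b = _gene_membership(uni, "b", merged_b, membership_rule)
        cvals = int(in_b.sum()), int((~in_b).sum())
    else:
        cvals = (0, 0)
    table = ContingencyTable(a=within, b=outside, c=cvals[0], d=cvals[1])
    res = fisher_exact(table)
    res.detail = {"n_excluded_intervals": excluded,
                  "chance_coverage": cvals[0] / max(1, sum(cvals))}
    return res


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values for a battery of tests."""
    from scipy.stats import false_discovery_control

    p = np.asarray(p_values, dtype=float)
    return false_discovery_control(p, method="bh")
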
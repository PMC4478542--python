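"""Synthetic structured inbred panels with haplotype-block LD, planted QTL,
multi-environment phenotypes, and collinear ortholog maps.

The generator emulates the statistical structure of a sorghum-style
association panel: a few hundred highly inbred accessions falling into a
handful of ancestry groups, genotyped at SNPs organised into haplotype blocks
whose length sets the LD decay extent (blocks are ~10x longer inside a
configurable pericentromeric span, mirroring suppressed recombination in
heterochromatin). Per block and subpopulation a small number of founder
haplotypes (2-8) is drawn from Balding-Nichols subpopulation allele
frequencies; accessions inherit two founder chains block-wise with a
recombination probability between adjacent blocks, and residual
heterozygosity is collapsed per locus at the inbreeding rate.

Phenotypes are additive: planted per-SNP effects plus an optional polygenic
term and optional subpopulation intercepts (structure confounding), with
environment-specific noise scaled so that the realized broad-sense
repeatability across environments matches ``target_h2``.

All randomness flows from ``rng_seed`` through named
``numpy.random.Generator`` streams; there is no global state.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .enrichment import OrthologPairSet
from .io import MISSING, GenotypeMatrix, PhenotypeTable, QtlInterval, snp_id_for

logger = logging.getLogger("seedgwas")


@dataclass
class SimulationConfig:
    n_accessions: int = 354
    n_subpops: int = 3
    fst_like_divergence: float = 0.2
    n_chromosomes: int = 2
    chrom_length_bp: int = 15_000_000
    n_snps: int = 3000
    ld_block_len_bp: int = 150_000
    inbreeding_rate: float = 0.98
    maf_floor: float = 0.05
    planted_qtl: list = field(default_factory=list)  # (chrom, pos_bp, effect, allele_freq)
    target_h2: float = 0.6
    n_environments: int = 1
    env_sd_multipliers: Optional[Sequence[float]] = None
    rng_seed: int = 0
    # generator shape knobs (defaults documented in the methods note)
    het_block_factor: float = 10.0
    het_span: Tuple[float, float] = (0.3, 0.7)
    founders_min: int = 2
    founders_max: int = 8
    between_block_recomb: float = 0.95
    tag_fraction: float = 0.8
    top_split_fraction: float = 0.4
    mid_arc_fraction: float = 0.4
    tag_mut_max: float = 0.05
    missing_rate: float = 0.0
    polygenic_var: float = 0.0
    polygenic_n_snps: int = 100
    subpop_effect_sd: float = 0.0

    def __post_init__(self):
        if self.env_sd_multipliers is None:
            self.env_sd_multipliers = [1.0] * self.n_environments
        self.env_sd_multipliers = [float(m) for m in self.env_sd_multipliers]
        self.validate()

    def chrom_names(self) -> List[str]:
        return [f"Sb{i + 1:02d}" for i in range(self.n_chromosomes)]

    def validate(self):
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if self.n_accessions < 2 or self.n_subpops < 1:
            raise ValueError("need >= 2 accessions and >= 1 subpopulation")
        if not 0 <= self.fst_like_divergence < 1:
            raise ValueError("fst_like_divergence must lie in [0, 1)")
        if not 0 <= self.inbreeding_rate <= 1:
            raise ValueError("inbreeding_rate must lie in [0, 1]")
        if not 0 <= self.maf_floor < 0.5:
            raise ValueError(
                "maf_floor makes the requested MAF spectrum infeasible (needs < 0.5)")
        if not 0 <= self.target_h2 <= 1:
            raise ValueError("target_h2 must lie in [0, 1]")
        if self.ld_block_len_bp > self.chrom_length_bp:
            raise ValueError("ld_block_len_bp must not exceed chrom_length_bp")
        if self.n_environments < 1 or len(self.env_sd_multipliers) != self.n_environments:
            raise ValueError("env_sd_multipliers must have one entry per environment")
        if any(m < 0 for m in self.env_sd_multipliers):
            raise ValueError("env_sd_multipliers must be non-negative")
        names = set(self.chrom_names())
        for q in self.planted_qtl:
            chrom, pos = q[0], int(q[1])
            if chrom not in names:
                raise ValueError(f"planted QTL on unknown chromosome {chrom!r}")
            if not 1 <= pos <= self.chrom_length_bp:
                raise ValueError(f"planted QTL position {pos} outside chromosome")


@dataclass
class SyntheticTruth:
    subpop_labels: np.ndarray                  # 1..k per accession
    causal_snps: list                          # (snp_id, effect) pairs
    true_qtl_intervals: list                   # QtlInterval covering each causal SNP
    realized_h2_per_env: Optional[list] = None


#: planted seed-size architecture for the panel emulation: six loci of modest
#: effect spread over two chromosomes, mirroring a trait controlled by many
#: genes with individual PVE in the 4-15% range
DEFAULT_PLANTED_QTL = [
    ("Sb01", 2_000_000, 1.2, 0.25),
    ("Sb01", 7_500_000, 1.0, 0.35),
    ("Sb01", 13_000_000, 0.9, 0.30),
    ("Sb02", 2_500_000, 1.1, 0.20),
    ("Sb02", 8_000_000, 0.95, 0.40),
    ("Sb02", 13_000_000, 0.85, 0.30),
]


def sap_like_config(rng_seed: int = 0, planted: bool = True,
                    **overrides) -> SimulationConfig:
    """Study conditions emulating a sorghum-style association panel at desk
    scale: 354 inbred accessions in three ancestry groups, SNPs every ~2.7 kb
    over two 15-Mb chromosomes (matching the genome-wide marker density of a
    ~265k-SNP panel on a 730-Mb genome), 150-kb LD blocks stretched 10x in the
    pericentromeric middle of each chromosome, and a multi-environment trait
    with heritability 0.3 from six planted loci of modest effect."""
    kwargs = dict(
        n_accessions=354, n_subpops=3, fst_like_divergence=0.15,
        n_chromosomes=2, chrom_length_bp=15_000_000, n_snps=11_000,
        ld_block_len_bp=150_000, inbreeding_rate=0.98, maf_floor=0.05,
        planted_qtl=list(DEFAULT_PLANTED_QTL) if planted else [],
        target_h2=0.3, n_environments=3, env_sd_multipliers=[1.0, 1.0, 1.0],
        rng_seed=rng_seed,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


def _block_edges(length_bp: int, base_len: int, het_factor: float,
                 het_span: Tuple[float, float]) -> np.ndarray:
    """Block boundaries along one chromosome; blocks inside the central
    (pericentromeric) span are het_factor times longer."""
    lo, hi = het_span[0] * length_bp, het_span[1] * length_bp
    edges = [0]
    while edges[-1] < length_bp:
        cur = edges[-1]
        step = base_len * het_factor if lo <= cur < hi else base_len
        edges.append(min(length_bp, cur + int(step)))
    return np.asarray(edges, dtype=np.int64)


def simulate_population(config: SimulationConfig) -> Tuple[GenotypeMatrix, SyntheticTruth]:
    """Generate the genotype matrix and ground truth for one panel."""
    config.validate()
    rng = np.random.default_rng([config.rng_seed, 11])
    n, k = config.n_accessions, config.n_subpops
    F = config.fst_like_divergence

    # subpopulation membership, contiguous and near-equal
    sizes = [n // k + (1 if i < n % k else 0) for i in range(k)]
    labels = np.repeat(np.arange(1, k + 1), sizes)
    members = [np.where(labels == g)[0] for g in range(1, k + 1)]

    # SNP positions per chromosome
    chroms = config.chrom_names()
    per_chrom = [config.n_snps // len(chroms)] * len(chroms)
    for i in range(config.n_snps % len(chroms)):
        per_chrom[i] += 1
    chrom_arr, pos_arr = [], []
    block_meta = []  # (chrom, start_bp, end_bp, snp_index_array)
    col2block = np.empty(config.n_snps, dtype=np.int64)
    for ci, chrom in enumerate(chroms):
        m = per_chrom[ci]
        pool = np.unique(rng.integers(1, config.chrom_length_bp + 1, size=max(2 * m, m + 16)))
        while len(pool) < m:
            pool = np.unique(np.concatenate(
                [pool, rng.integers(1, config.chrom_length_bp + 1, size=m)]))
        pos = np.sort(rng.choice(pool, size=m, replace=False))
        edges = _block_edges(config.chrom_length_bp, config.ld_block_len_bp,
                             config.het_block_factor, config.het_span)
        which = np.searchsorted(edges, pos, side="right") - 1
        offset = len(chrom_arr)
        for b in range(len(edges) - 1):
            sel = np.where(which == b)[0]
            col2block[sel + offset] = len(block_meta)
            block_meta.append((chrom, int(edges[b] + 1), int(edges[b + 1]),
                               sel + offset))
        chrom_arr.extend([chrom] * m)
        pos_arr.extend(pos.tolist())
    chrom_arr = np.asarray(chrom_arr, dtype=object)
    pos_arr = np.asarray(pos_arr, dtype=np.int64)
    snp_ids = [snp_id_for(c, p) for c, p in zip(chrom_arr, pos_arr)]

    # ancestral and subpopulation allele frequencies (Balding-Nichols)
    p0 = rng.uniform(max(config.maf_floor, 0.02) + 0.03, 0.5, size=config.n_snps)
    psub = _subpop_freqs(rng, p0, k, F)

    # resolve planted QTL to SNP columns up front: their blocks get an anchor
    # arc whose frequency matches the requested causal allele frequency
    planted_cols = []      # (col, block_id, effect, target_freq)
    anchor_by_block = {}
    for q in config.planted_qtl:
        chrom, pos, effect, freq = q[0], int(q[1]), float(q[2]), float(q[3])
        col = _nearest_snp(chrom, pos, chrom_arr, pos_arr)
        block_id = int(col2block[col])
        half_block = (block_meta[block_id][2] - block_meta[block_id][1] + 1) / 2
        if abs(int(pos_arr[col]) - pos) > half_block:
            raise ValueError(
                f"no SNP within half a block length of planted QTL {chrom}:{pos}")
        planted_cols.append((col, block_id, effect, freq))
        anchor_by_block[block_id] = freq

    # founder haplotypes per block x subpop, founder-chain assignments per chain.
    # Each block carries a random hierarchical clade tree over its founder
    # haplotypes (shared across subpopulations): "tag" SNPs mark clades of the
    # tree — a configurable majority mark the top bipartition, the rest nested
    # sub-clades — giving the graded, nested LD of real haplotype blocks. The
    # remaining SNPs segregate independently at the Balding-Nichols
    # subpopulation frequencies.
    counts = np.zeros((n, config.n_snps), dtype=np.int16)
    founder_alleles = []   # per block: list over subpops of (n_f, m_b) arrays
    block_orders = []      # per block: leaf order, list of (subpop, founder)
    block_trees = []       # per block: clade intervals of the founder tree
    assignments = []       # per block: (2, n) founder index per chain
    collapse_dirs = []     # per block: (n,) chain fixed by selfing
    prev_assign = None
    prev_chrom = None
    for bid, (chrom, start, end, sel) in enumerate(block_meta):
        n_f = int(rng.integers(config.founders_min, config.founders_max + 1))
        m_b = len(sel)
        alleles, order, tree = _block_founders(
            rng, k, n_f, [psub[g][sel] for g in range(k)],
            tag_fraction=config.tag_fraction,
            top_split_fraction=config.top_split_fraction,
            mid_arc_fraction=config.mid_arc_fraction,
            mut_max=config.tag_mut_max,
            subpop_clustered=bool(rng.random() < F),
            anchor_frac=anchor_by_block.get(bid))
        assign = np.zeros((2, n), dtype=np.int32)
        for chain in (0, 1):
            fresh = rng.integers(0, n_f, size=n)
            if prev_assign is None or prev_chrom != chrom:
                assign[chain] = fresh
            else:
                keep = rng.random(n) >= config.between_block_recomb
                carried = prev_assign[chain] % n_f
                assign[chain] = np.where(keep, carried, fresh)
        # per accession and block, residual heterozygosity collapses toward one
        # chain drawn once per block (selfing fixes a haplotype, preserving LD)
        dirs = rng.integers(0, 2, size=n)
        if len(sel):
            for g in range(k):
                idx = members[g]
                counts[np.ix_(idx, sel)] = _genotype_from_founders(
                    alleles[g], assign[0][idx], assign[1][idx], dirs[idx],
                    config.inbreeding_rate, rng)
        founder_alleles.append(alleles)
        block_orders.append(order)
        block_trees.append(tree)
        assignments.append(assign)
        collapse_dirs.append(dirs)
        prev_assign, prev_chrom = assign, chrom

    # plant causal SNPs at the founder level
    causal: List[Tuple[int, float]] = []   # (snp column, effect)
    for col, block_id, effect, freq in planted_cols:
        _plant_allele(counts, col, block_id, founder_alleles,
                      block_orders, block_trees, assignments, collapse_dirs,
                      block_meta, members, config.inbreeding_rate, rng)
        causal.append((col, effect))

    _enforce_maf_floor(counts, config, rng, founder_alleles, assignments,
                       collapse_dirs, block_meta, members, col2block,
                       protected={c for c, _ in causal})

    if config.missing_rate > 0:
        mask = rng.random(counts.shape) < config.missing_rate
        counts[mask] = MISSING

    # orient stored counts to the minor allele; effects follow the stored allele
    freq = _called_freq(counts)
    flip = freq > 0.5
    if flip.any():
        cols = counts[:, flip]
        counts[:, flip] = np.where(cols == MISSING, MISSING, 2 - cols)
    effects = {col: (-e if flip[col] else e) for col, e in causal}

    accession_ids = [f"acc{i + 1:04d}" for i in range(n)]
    gm = GenotypeMatrix(accession_ids, snp_ids, chrom_arr, pos_arr, counts)

    true_intervals = []
    for col, _ in causal:
        bid = int(col2block[col])
        chrom, start, end, _sel = block_meta[bid]
        true_intervals.append(QtlInterval(chrom=chrom, start_bp=start, end_bp=end,
                                          trait_name="sim_trait", source_study="truth"))
    truth = SyntheticTruth(
        subpop_labels=labels,
        causal_snps=[(snp_ids[col], effects[col]) for col, _ in causal],
        true_qtl_intervals=true_intervals,
    )
    return gm, truth


def _subpop_freqs(rng, p0, k, F):
    if F < 1e-12 or k == 1:
        return [p0.copy() for _ in range(k)]
    a = p0 * (1 - F) / F
    b = (1 - p0) * (1 - F) / F
    return [np.clip(rng.beta(a, b), 1e-4, 1 - 1e-4) for _ in range(k)]


def _genotype_from_founders(alleles, a0, a1, dirs, inbreeding_rate, rng):
    """Diploid counts from two founder chains; heterozygous loci collapse with
    probability ``inbreeding_rate`` toward the chain fixed by selfing."""
    g0 = alleles[a0]
    g1 = alleles[a1]
    s = (g0 + g1).astype(np.int16)
    het = g0 != g1
    if het.any() and inbreeding_rate > 0:
        collapse = het & (rng.random(s.shape) < inbreeding_rate)
        fixed = np.where(dirs[:, None].astype(bool), g1, g0)
        s[collapse] = (2 * fixed[collapse]).astype(np.int16)
    return s


def _nearest_snp(chrom, pos, chrom_arr, pos_arr):
    on = np.where(np.asarray(chrom_arr, dtype=object) == chrom)[0]
    if len(on) == 0:
        raise ValueError(f"no SNPs on chromosome {chrom}")
    return int(on[np.argmin(np.abs(np.asarray(pos_arr)[on] - pos))])


def _block_founders(rng, k, n_f, p_block, tag_fraction, top_split_fraction,
                    mid_arc_fraction, mut_max, subpop_clustered,
                    anchor_frac=None):
    """Founder haplotypes for one block under an arc-haplotype model.

    Leaves are the k*n_f (subpopulation, founder) slots, ordered either
    interleaved across subpopulations (ancestry-balanced haplotype splits) or
    subpopulation-contiguous (splits align with ancestry — the divergent
    case). Every tag SNP marks a contiguous arc of the leaf order: with
    probability ``top_split_fraction`` the block's anchor arc (its major
    haplotype split), otherwise a random arc — partially overlapping arcs give
    the dense continuum of pairwise r² seen in real blocks. A small per-SNP,
    per-founder mutation rate roughens the tags; non-tag SNPs segregate
    independently at the Balding-Nichols subpopulation frequencies.

    ``anchor_frac`` fixes the anchor-arc frequency (used for blocks that carry
    a planted causal variant). Returns (per-subpop allele arrays, leaf order,
    arcs) with the anchor arc first.
    """
    NF = k * n_f
    m = len(p_block[0])
    if subpop_clustered:
        order = [(g, f) for g in range(k) for f in range(n_f)]
    else:
        order = [(g, f) for f in range(n_f) for g in range(k)]

    def random_arc(min_frac=0.1, max_frac=0.9, length_frac=None):
        frac = length_frac if length_frac is not None else rng.uniform(min_frac, max_frac)
        length = int(np.clip(round(frac * NF), 1, NF - 1))
        start = int(rng.integers(0, NF - length + 1))
        return (start, start + length)

    anchor = random_arc(0.25, 0.75, length_frac=anchor_frac)

    def perturbed_arc():
        # a recombinant derivative of the anchor: each end shifted by 15-55%
        # of the anchor length, giving intermediate r2 to the anchor
        a, b = anchor
        L = b - a
        na = a + int(round(rng.uniform(-0.55, 0.55) * L))
        nb = b + int(round(rng.uniform(-0.55, 0.55) * L))
        na = max(0, min(na, NF - 2))
        nb = max(na + 1, min(nb, NF))
        return (na, nb)

    tag = rng.random(m) < tag_fraction
    arcs = [anchor]
    leaf_alleles = np.zeros((NF, m), dtype=np.int8)
    u_cat = rng.random(m)
    for s in range(m):
        if not tag[s]:
            continue
        if u_cat[s] < top_split_fraction:
            a, b = anchor
        elif u_cat[s] < top_split_fraction + mid_arc_fraction:
            a, b = perturbed_arc()
            arcs.append((a, b))
        else:
            a, b = random_arc()
            arcs.append((a, b))
        leaf_alleles[a:b, s] = 1
    eps = rng.uniform(0.0, max(mut_max, 1e-9), size=m)
    mut = tag[None, :] & (rng.random((NF, m)) < eps[None, :])
    leaf_alleles ^= mut
    alleles = [np.zeros((n_f, m), dtype=np.int8) for _ in range(k)]
    for pos, (g, f) in enumerate(order):
        row = leaf_alleles[pos].copy()
        nontag = ~tag
        if nontag.any():
            row[nontag] = rng.random(int(nontag.sum())) < p_block[g][nontag]
        alleles[g][f] = row
    return alleles, order, arcs


def _plant_allele(counts, col, block_id, founder_alleles,
                  block_orders, block_trees, assignments, collapse_dirs,
                  block_meta, members, inbreeding_rate, rng):
    """Plant a causal allele as the block's anchor-arc haplotype indicator.

    The block was generated with its anchor arc sized to the requested causal
    allele frequency, so the causal variant rides the block's major haplotype
    split and the tag SNPs surround it with graded LD (anchor copies at high
    r², partially overlapping arcs at intermediate r²). The causal SNP column
    is rebuilt, mutation-free, from that carrier set."""
    chrom, start, end, sel = block_meta[block_id]
    assign = assignments[block_id]
    order = block_orders[block_id]
    a, b = block_trees[block_id][0]  # the anchor arc
    chosen = set(order[a:b])
    j_local = int(np.where(sel == col)[0][0])
    for g, idx in enumerate(members):
        alle = founder_alleles[block_id][g]
        n_f = alle.shape[0]
        carrier = np.array([(g, f) in chosen for f in range(n_f)], dtype=np.int8)
        alle[:, j_local] = carrier
        counts[idx, col] = _genotype_from_founders(
            alle[:, [j_local]], assign[0][idx], assign[1][idx],
            collapse_dirs[block_id][idx], inbreeding_rate, rng)[:, 0]


def _called_freq(counts):
    called = counts != MISSING
    ncall = np.maximum(called.sum(axis=0), 1)
    return np.where(called, counts, 0).sum(axis=0) / (2 * ncall)


def _enforce_maf_floor(counts, config, rng, founder_alleles, assignments,
                       collapse_dirs, block_meta, members, col2block, protected):
    """Redraw founder alleles for SNPs below the MAF floor; inject homozygous
    minor genotypes as a last resort so the invariant holds exactly."""
    for attempt in range(12):
        freq = _called_freq(counts)
        maf = np.minimum(freq, 1 - freq)
        bad = [j for j in np.where(maf < config.maf_floor)[0] if j not in protected]
        if not bad:
            break
        for col in bad:
            bid = int(col2block[col])
            sel = block_meta[bid][3]
            j_local = int(np.where(sel == col)[0][0])
            p_new = rng.uniform(0.25, 0.5)
            assign = assignments[bid]
            for g, idx in enumerate(members):
                alle = founder_alleles[bid][g]
                alle[:, j_local] = (rng.random(alle.shape[0]) < p_new).astype(np.int8)
                counts[idx, col] = _genotype_from_founders(
                    alle[:, [j_local]], assign[0][idx], assign[1][idx],
                    collapse_dirs[bid][idx], config.inbreeding_rate, rng)[:, 0]
    # final injection for any SNP still below the floor (incl. protected ones)
    freq = _called_freq(counts)
    maf = np.minimum(freq, 1 - freq)
    for col in np.where(maf < config.maf_floor)[0]:
        colv = counts[:, col]
        called = colv != MISSING
        minor_is_alt = freq[col] <= 0.5
        minor_alleles = int(colv[called].sum()) if minor_is_alt \
            else int(2 * called.sum() - colv[called].sum())
        floor_alleles = math.ceil(config.maf_floor * 2 * int(called.sum()))
        need = math.ceil(max(0, floor_alleles - minor_alleles) / 2)
        if need == 0:
            continue
        lo_val, hi_val = (0, 2) if minor_is_alt else (2, 0)
        donors = np.where(colv == lo_val)[0]
        take = rng.choice(donors, size=min(len(donors), need), replace=False)
        counts[take, col] = hi_val


def simulate_phenotypes(gm: GenotypeMatrix, truth: SyntheticTruth,
                        config: SimulationConfig,
                        trait_name: str = "sim_trait") -> PhenotypeTable:
    """Additive phenotypes per accession and environment.

    value = sum(effect * minor-allele count) + polygenic term
            + subpopulation intercept + environment-scaled noise,
    with the noise variance set from the realized genetic variance so the
    broad-sense repeatability across environments matches ``target_h2``.
    Updates ``truth.realized_h2_per_env`` in place.
    """
    if config.target_h2 == 1.0 and config.n_environments > 1 and \
            any(m > 0 for m in config.env_sd_multipliers):
        raise ValueError("target_h2=1 with multiple environments and nonzero "
                         "noise multipliers is contradictory")
    rng = np.random.default_rng([config.rng_seed, 23])
    n = gm.n_accessions
    G = np.zeros(n)
    X = gm.counts.astype(float)
    X[X == MISSING] = np.nan
    col_mean = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), col_mean, X)
    causal_cols = []
    for snp_id, effect in truth.causal_snps:
        j = gm.snp_index(snp_id)
        causal_cols.append(j)
        G += effect * X[:, j]
    if config.polygenic_var > 0:
        pool = np.setdiff1d(np.arange(gm.n_snps), np.array(causal_cols, dtype=int))
        take = rng.choice(pool, size=min(config.polygenic_n_snps, len(pool)),
                          replace=False)
        w = rng.normal(size=len(take))
        poly = (X[:, take] - X[:, take].mean(axis=0)) @ w
        sd = poly.std()
        if sd > 0:
            G += poly * math.sqrt(config.polygenic_var) / sd
    if config.subpop_effect_sd > 0:
        shifts = rng.normal(0.0, config.subpop_effect_sd,
                            size=int(truth.subpop_labels.max()))
        G += shifts[truth.subpop_labels - 1]

    var_g = float(G.var(ddof=1))
    mults = np.asarray(config.env_sd_multipliers, dtype=float)
    if var_g == 0.0:
        sigma = 1.0
    elif config.target_h2 >= 1.0:
        sigma = 0.0
    elif config.target_h2 == 0.0:
        # no accession-level signal requested: drown the genetic term
        sigma = math.sqrt(var_g) * 1e3
    else:
        mean_m2 = float(np.mean(mults ** 2)) if np.any(mults > 0) else 1.0
        sigma = math.sqrt(var_g * (1 - config.target_h2)
                          / (config.target_h2 * mean_m2))

    rows = []
    realized = []
    for e in range(config.n_environments):
        noise = rng.normal(0.0, 1.0, size=n) * mults[e] * sigma
        y = G + noise
        env = f"env{e + 1}"
        rows.append(pd.DataFrame({
            "accession_id": gm.accession_ids, "trait": trait_name,
            "environment": env, "value": y,
        }))
        denom = var_g + (mults[e] * sigma) ** 2
        realized.append(var_g / denom if denom > 0 else 0.0)
    truth.realized_h2_per_env = realized
    return PhenotypeTable(pd.concat(rows, ignore_index=True))


def simulate_ortholog_map(n_genes: int, genome_a_layout: Dict[str, int],
                          genome_b_layout: Dict[str, int],
                          inversion_rate: float = 0.0, loss_rate: float = 0.0,
                          rng_seed: int = 0, run_length: int = 100,
                          gene_len_bp: int = 3000,
                          planted_blocks: Optional[list] = None) -> OrthologPairSet:
    """Collinear ortholog gene pairs between two genomes.

    Genes come in collinear runs assigned cyclically to chromosome pairs;
    within a run positions increase in both genomes (order reversed in genome
    B for inverted runs). A ``loss_rate`` fraction of genes lacks a partner
    and is dropped from the pair table. ``planted_blocks`` is a list of
    ((chrom_a, start_a, end_a), (chrom_b, start_b, end_b), n_genes) tuples
    whose genes are placed inside both intervals — a planted correspondence.
    """
    if loss_rate >= 1:
        raise ValueError("loss_rate must be < 1")
    if not 0 <= inversion_rate <= 1:
        raise ValueError("inversion_rate must lie in [0, 1]")
    rng = np.random.default_rng([rng_seed, 37])
    chroms_a = sorted(genome_a_layout)
    chroms_b = sorted(genome_b_layout)
    n_runs = max(1, math.ceil(n_genes / run_length))
    runs = []
    left = n_genes
    for r in range(n_runs):
        size = min(run_length, left)
        left -= size
        runs.append({"chrom_a": chroms_a[r % len(chroms_a)],
                     "chrom_b": chroms_b[r % len(chroms_b)],
                     "size": size,
                     "inverted": bool(rng.random() < inversion_rate)})

    per_chrom_a = {c: [r for r in runs if r["chrom_a"] == c] for c in chroms_a}
    per_chrom_b = {c: [r for r in runs if r["chrom_b"] == c] for c in chroms_b}

    def lay_out(per_chrom, layout, key):
        for c, rr in per_chrom.items():
            if not rr:
                continue
            seg = layout[c] // len(rr)
            for i, r in enumerate(rr):
                lo = i * seg + 1
                hi = min((i + 1) * seg, layout[c]) - gene_len_bp
                starts = np.linspace(lo, max(lo + 1, hi), r["size"]).astype(np.int64)
                r[key] = starts

    lay_out(per_chrom_a, genome_a_layout, "starts_a")
    lay_out(per_chrom_b, genome_b_layout, "starts_b")

    rows = []
    gid = 0
    for r in runs:
        sb = r["starts_b"][::-1] if r["inverted"] else r["starts_b"]
        for i in range(r["size"]):
            gid += 1
            rows.append({
                "gene_a": f"GA{gid:05d}", "chrom_a": r["chrom_a"],
                "start_a": int(r["starts_a"][i]),
                "end_a": int(r["starts_a"][i]) + gene_len_bp - 1,
                "gene_b": f"GB{gid:05d}", "chrom_b": r["chrom_b"],
                "start_b": int(sb[i]), "end_b": int(sb[i]) + gene_len_bp - 1,
                "strand": "-" if r["inverted"] else "+",
            })
    if planted_blocks:
        for (iv_a, iv_b, size) in planted_blocks:
            ca, sa, ea = iv_a
            cb, sbp, eb = iv_b
            pa = np.linspace(sa, max(sa + 1, ea - gene_len_bp), size).astype(np.int64)
            pb = np.linspace(sbp, max(sbp + 1, eb - gene_len_bp), size).astype(np.int64)
            for i in range(size):
                gid += 1
                rows.append({
                    "gene_a": f"GA{gid:05d}", "chrom_a": ca,
                    "start_a": int(pa[i]), "end_a": int(pa[i]) + gene_len_bp - 1,
                    "gene_b": f"GB{gid:05d}", "chrom_b": cb,
                    "start_b": int(pb[i]), "end_b": int(pb[i]) + gene_len_bp - 1,
                    "strand": "+",
                })
    df = pd.DataFrame(rows)
    keep = rng.random(len(df)) >= loss_rate
    df = df[keep].reset_index(drop=True)
    return OrthologPairSet(df)


def write_truth(truth: SyntheticTruth, path) -> None:
    """Tab-delimited ground-truth sidecar (labels, causal SNPs, intervals)."""
    with open(path, "w") as fh:
        fh.write("#subpop_labels\t" + ",".join(map(str, truth.subpop_labels)) + "\n")
        for snp_id, eff in truth.causal_snps:
            fh.write(f"causal\t{snp_id}\t{eff:g}\n")
        for iv in truth.true_qtl_intervals:
            fh.write(f"interval\t{iv.chrom}\t{iv.start_bp}\t{iv.end_bp}\n")
        if truth.realized_h2_per_env is not None:
            fh.write("#realized_h2\t" + ",".join(f"{h:.4f}" for h in
                                                 truth.realized_h2_per_env) + "\n")
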
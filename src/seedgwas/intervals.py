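"""Interval algebra, QTL anchoring, and association-hotspot detection.

A hotspot is an association region built from a "seed" SNP at or below a
stringent p-value threshold together with at least ``min_support`` minor
significant SNPs (p in the band just above the seed threshold) that are in
strong LD with the seed; the span of seed plus linked minors sets the
boundary. Both thresholds are inclusive: seeds satisfy p <= seed_threshold and
minors satisfy seed_threshold < p <= minor_lower.

QTL likelihood intervals from linkage maps are anchored to physical
coordinates by scanning outward from the likelihood-peak marker in genetic
order and taking, on each side, the first marker with alignment information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .io import GenotypeMatrix, MarkerMapEntry, QtlInterval, AssociationResult
from .ld import pairwise_r2

logger = logging.getLogger("seedgwas")


@dataclass
class HotspotConfig:
    seed_threshold: float = 1e-5
    minor_lower: float = 1e-3
    link_threshold: float = 0.5
    min_support: int = 10
    max_link_dist_bp: int = 2_000_000
    merge_overlapping: bool = True

    def __post_init__(self):
        if not self.seed_threshold < self.minor_lower:
            raise ValueError("seed_threshold must be < minor_lower")
        if not 0 < self.link_threshold <= 1:
            raise ValueError("link_threshold must lie in (0,1]")


@dataclass
class Hotspot:
    trait_name: str
    chrom: str
    start_bp: int
    end_bp: int
    seed_snps: list
    linked_minor_snps: list

    @property
    def n_linked_minor(self) -> int:
        return len(self.linked_minor_snps)

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass
class AnchoredInterval:
    interval: QtlInterval
    peak_marker_id: str
    left_marker_id: Optional[str]
    right_marker_id: Optional[str]
    one_sided: bool = False


def anchor_qtl_interval(markers: Sequence[MarkerMapEntry], peak_marker_id: str,
                        chrom_end_bp: Optional[int] = None,
                        trait_name: str = "", source_study: str = "") -> AnchoredInterval:
    """Physical interval for a likelihood peak from the nearest aligned flankers.

    Markers are taken in genetic order within the peak's linkage group.
    Scanning outward from the peak on each side, the first flanking marker
    with alignment information bounds the interval; if a side has no aligned
    flanker the (aligned) peak itself may serve as that bound, and failing
    that the interval is flagged one-sided and extended to the chromosome end
    (position 1 on the left).
    """
    peak = next((m for m in markers if m.marker_id == peak_marker_id), None)
    if peak is None:
        raise ValueError(f"peak marker {peak_marker_id!r} not in map")
    group = sorted(
        (m for m in markers if m.linkage_group == peak.linkage_group),
        key=lambda m: m.genetic_pos_cM,
    )
    k = next(i for i, m in enumerate(group) if m.marker_id == peak_marker_id)

    def first_aligned(indices):
        for i in indices:
            if group[i].has_alignment:
                return group[i]
        return None

    left = first_aligned(range(k - 1, -1, -1))
    right = first_aligned(range(k + 1, len(group)))
    if left is None and peak.has_alignment:
        left = peak
    if right is None and peak.has_alignment:
        right = peak
    if left is None and right is None:
        raise ValueError("no aligned marker in the peak's linkage group")
    anchored = [m for m in (left, right) if m is not None]
    chroms = {m.chrom for m in anchored}
    if len(chroms) > 1:
        raise ValueError(
            f"discordant anchoring: flanking aligned markers on {sorted(chroms)}"
        )
    chrom = anchored[0].chrom
    one_sided = left is None or right is None
    lo = left.pos_bp if left is not None else 1
    if right is not None:
        hi = right.pos_bp
    else:
        if chrom_end_bp is None:
            raise ValueError("one-sided interval needs chrom_end_bp")
        hi = chrom_end_bp
    start, end = min(lo, hi), max(lo, hi)
    iv = QtlInterval(chrom=chrom, start_bp=int(start), end_bp=int(end),
                     trait_name=trait_name, source_study=source_study)
    return AnchoredInterval(
        interval=iv, peak_marker_id=peak_marker_id,
        left_marker_id=left.marker_id if left else None,
        right_marker_id=right.marker_id if right else None,
        one_sided=one_sided,
    )


def detect_hotspots(assoc: AssociationResult, gm: GenotypeMatrix,
                    cfg: HotspotConfig = HotspotConfig()) -> List[Hotspot]:
    """Seed/linked-minor hotspot calling.

    For every seed SNP (p <= seed_threshold), minor significant SNPs
    (seed_threshold < p <= minor_lower) on the same chromosome within
    ``max_link_dist_bp`` and with r² >= link_threshold to the seed are
    collected; the seed emits a hotspot when it gathers at least
    ``min_support`` linked minors. Seeds sharing a linked minor or with
    overlapping spans are merged into one hotspot (union of members) when
    ``merge_overlapping`` is set.
    """
    df = assoc.df.dropna(subset=["p_value"])
    id_to_col = {s: j for j, s in enumerate(gm.snp_ids)}

    seeds = df[df["p_value"] <= cfg.seed_threshold]
    minors = df[(df["p_value"] > cfg.seed_threshold) & (df["p_value"] <= cfg.minor_lower)]

    proto = []  # (members frozenset, seed ids, minor ids, chrom, span)
    for _, s in seeds.iterrows():
        sid = s["snp_id"]
        j = id_to_col.get(sid)
        if j is None:
            logger.warning("seed %s not in genotype matrix; skipped", sid)
            continue
        col = gm.counts[:, j]
        called = col[col >= 0]
        if called.size == 0 or np.ptp(called) == 0:
            logger.warning("seed %s monomorphic; skipped", sid)
            continue
        cand = minors[(minors["chrom"] == s["chrom"]) &
                      (np.abs(minors["pos_bp"] - s["pos_bp"]) <= cfg.max_link_dist_bp)]
        linked, positions = [], [int(s["pos_bp"])]
        for _, m in cand.iterrows():
            if m["snp_id"] not in id_to_col:
                continue
            r2 = pairwise_r2(gm, sid, m["snp_id"])
            if not np.isnan(r2) and r2 >= cfg.link_threshold:
                linked.append(m["snp_id"])
                positions.append(int(m["pos_bp"]))
        if len(linked) >= cfg.min_support:
            proto.append({
                "seeds": {sid}, "minors": set(linked), "chrom": s["chrom"],
                "start": min(positions), "end": max(positions),
            })

    if cfg.merge_overlapping:
        proto = _merge_proto_hotspots(proto)
    proto.sort(key=lambda h: (str(h["chrom"]), h["start"]))
    return [
        Hotspot(trait_name=assoc.trait_name, chrom=h["chrom"],
                start_bp=h["start"], end_bp=h["end"],
                seed_snps=sorted(h["seeds"]), linked_minor_snps=sorted(h["minors"]))
        for h in proto
    ]


def _merge_proto_hotspots(proto):
    merged = True
    while merged:
        merged = False
        out = []
        for h in proto:
            hit = None
            for o in out:
                if o["chrom"] != h["chrom"]:
                    continue
                share = (o["seeds"] | o["minors"]) & (h["seeds"] | h["minors"])
                overlap = max(o["start"], h["start"]) <= min(o["end"], h["end"])
                if share or overlap:
                    hit = o
                    break
            if hit is None:
                out.append(dict(h))
            else:
                hit["seeds"] |= h["seeds"]
                hit["minors"] |= h["minors"]
                hit["start"] = min(hit["start"], h["start"])
                hit["end"] = max(hit["end"], h["end"])
                merged = True
        proto = out
    return proto


def interval_overlap(a, b) -> int:
    """Shared bp between two 1-based inclusive intervals; 0 when disjoint or on
    different chromosomes."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end_bp, b.end_bp) - max(a.start_bp, b.start_bp) + 1)


def merge_intervals(intervals: Sequence[QtlInterval]) -> List[QtlInterval]:
    """Union of overlapping (>= 1 shared bp, same chromosome) intervals.

    Output is sorted and pairwise disjoint; touching-but-not-overlapping
    intervals stay separate under inclusive coordinates.
    """
    if not intervals:
        return []
    svals = sorted(intervals, key=lambda iv: (str(iv.chrom), iv.start_bp, iv.end_bp))
    out = [QtlInterval(chrom=svals[0].chrom, start_bp=svals[0].start_bp,
                       end_bp=svals[0].end_bp)]
    for iv in svals[1:]:
        cur = out[-1]
        if iv.chrom == cur.chrom and iv.start_bp <= cur.end_bp:
            cur.end_bp = max(cur.end_bp, iv.end_bp)
        else:
            out.append(QtlInterval(chrom=iv.chrom, start_bp=iv.start_bp, end_bp=iv.end_bp))
    return out


def refinement_ratio(qtl: QtlInterval, hotspot) -> float:
    """Length ratio QTL / hotspot for a co-localized pair (how much the
    association evidence shrinks the linkage interval)."""
    hs_iv = QtlInterval(chrom=hotspot.chrom, start_bp=hotspot.start_bp,
                        end_bp=hotspot.end_bp)
    if qtl.chrom != hs_iv.chrom or interval_overlap(qtl, hs_iv) == 0:
        raise ValueError("non-colocalized pair")
    return qtl.length_bp / hs_iv.length_bp
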
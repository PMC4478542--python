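#!/usr/bin/env python
"""Simulate the study panel.

Builds the sorghum-style association panel emulation (354 inbred accessions,
three ancestry groups, ~2.7-kb SNP spacing over two 15-Mb chromosomes with
150-kb LD blocks stretched 10x in pericentromeric regions), a seed-size-like
trait measured in three environments with heritability 0.3 from six planted
loci, and a collinear ortholog map to a second genome with a planted
corresponding region.

Writes genotypes to scratch/ (large) and phenotypes, ground truth and the
ortholog table to results/.
"""

from pathlib import Path

from seedgwas import io as gio
from seedgwas.enrichment import write_ortholog_pairs
from seedgwas.simulate import (sap_like_config, simulate_ortholog_map,
                               simulate_phenotypes, simulate_population,
                               write_truth)

SEED = 1
ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "panel"
RESULTS = ROOT / "results"


def main():
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    cfg = sap_like_config(rng_seed=SEED)
    gm, truth = simulate_population(cfg)
    pt = simulate_phenotypes(gm, truth, cfg, trait_name="seed_size")
    gio.write_genotypes(gm, SCRATCH / "genotypes.tsv", "matrix_tsv")
    gio.write_phenotypes(pt, RESULTS / "phenotypes.tsv")
    write_truth(truth, RESULTS / "truth.tsv")
    gio.write_intervals(truth.true_qtl_intervals, RESULTS / "true_qtl.bed", "bed")

    # cross-genome ortholog map: genes collinear with a second (rice-like)
    # genome, with a planted correspondence at the first true QTL interval
    iv = truth.true_qtl_intervals[0]
    region_b = ("Os02", 3_000_000, 3_000_000 + max(400_000, iv.length_bp))
    orth = simulate_ortholog_map(
        500, {iv.chrom: cfg.chrom_length_bp}, {"Os02": 8_000_000},
        loss_rate=0.1, rng_seed=SEED,
        planted_blocks=[((iv.chrom, iv.start_bp, iv.end_bp), region_b, 40)])
    write_ortholog_pairs(orth, RESULTS / "orthologs.tsv")
    gio.write_intervals(
        [gio.QtlInterval(chrom=region_b[0], start_bp=region_b[1], end_bp=region_b[2])],
        RESULTS / "foreign_qtl.bed", "bed")

    print(f"panel: {gm.n_accessions} accessions x {gm.n_snps} SNPs "
          f"({len(set(gm.chrom))} chromosomes)")
    print(f"planted loci: {len(truth.causal_snps)}; "
          f"realized per-environment h2: "
          f"{[round(float(h), 3) for h in truth.realized_h2_per_env]}")
    print(f"ortholog pairs: {len(orth.df)} (planted correspondence at "
          f"{iv.chrom}:{iv.start_bp}-{iv.end_bp} <-> "
          f"{region_b[0]}:{region_b[1]}-{region_b[2]})")
    print(f"genotypes -> {SCRATCH / 'genotypes.tsv'}")


if __name__ == "__main__":
    main()
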
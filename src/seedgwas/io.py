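"""Core data model and file I/O.

All coordinate-carrying types are 1-based inclusive internally (genome-browser
convention); only BED input/output converts to/from 0-based half-open. Genotypes
are stored as minor-allele dosage counts in {0, 1, 2} with ``-1`` marking a
missing call; the minor allele is defined per SNP as the less frequent allele
over non-missing calls, ties broken toward the alternate allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("seedgwas")

MISSING = -1


def _chrom_sort_key(chrom: str):
    """Sort chromosomes numerically when they share an alphabetic prefix."""
    digits = "".join(ch for ch in chrom if ch.isdigit())
    prefix = "".join(ch for ch in chrom if not ch.isdigit())
    return (prefix, int(digits) if digits else -1)


def snp_id_for(chrom: str, pos_bp: int) -> str:
    """Canonical SNP identifier, e.g. ``S10_40095764`` for Sb10:40095764."""
    digits = "".join(ch for ch in chrom if ch.isdigit())
    token = str(int(digits)) if digits else chrom
    return f"S{token}_{int(pos_bp)}"


@dataclass
class GenotypeMatrix:
    """Accessions x SNPs minor-allele count matrix with positions and MAF."""

    accession_ids: list
    snp_ids: list
    chrom: np.ndarray
    pos_bp: np.ndarray
    counts: np.ndarray  # (n_accessions, n_snps), int, -1 = missing
    maf: np.ndarray = None

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.accession_ids), len(self.snp_ids)):
            raise ValueError("counts dimensions do not match id lists")
        order = sorted(
            range(len(self.snp_ids)),
            key=lambda j: (_chrom_sort_key(self.chrom[j]), self.pos_bp[j]),
        )
        if order != list(range(len(self.snp_ids))):
            self.snp_ids = [self.snp_ids[j] for j in order]
            self.chrom = self.chrom[order]
            self.pos_bp = self.pos_bp[order]
            self.counts = self.counts[:, order]
            if self.maf is not None:
                self.maf = np.asarray(self.maf)[order]
        if self.maf is None:
            self.maf = self.compute_maf()
        else:
            self.maf = np.asarray(self.maf, dtype=float)

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def compute_maf(self) -> np.ndarray:
        """Minor-allele frequency per SNP from the stored counts."""
        cts = self.counts
        valid = cts != MISSING
        n_called = valid.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(valid, cts, 0).sum(axis=0) / np.maximum(2 * n_called, 1)
        freq = np.where(n_called == 0, np.nan, freq)
        return freq

    @classmethod
    def from_counts(cls, accession_ids, snp_ids, chrom, pos_bp, counts):
        """Build a matrix, flipping columns so counts track the minor allele."""
        counts = np.asarray(counts).copy()
        obj = cls(list(accession_ids), list(snp_ids), chrom, pos_bp, counts)
        freq = obj.compute_maf()
        flip = freq > 0.5
        if flip.any():
            cols = obj.counts[:, flip]
            cols = np.where(cols == MISSING, MISSING, 2 - cols)
            obj.counts[:, flip] = cols
        obj.maf = obj.compute_maf()
        return obj

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"unknown SNP id: {snp_id}") from None

    def column(self, snp_id: str) -> np.ndarray:
        return self.counts[:, self.snp_index(snp_id)]

    def snps_in_region(self, chrom: str, start_bp: int, end_bp: int) -> np.ndarray:
        """Indices of SNPs with chrom match and start_bp <= pos <= end_bp."""
        return np.where(
            (self.chrom == chrom) & (self.pos_bp >= start_bp) & (self.pos_bp <= end_bp)
        )[0]


@dataclass
class PhenotypeTable:
    """Long-format trait table: one value per (accession, trait, environment)."""

    df: pd.DataFrame  # columns: accession_id, trait, environment, value

    COLUMNS = ("accession_id", "trait", "environment", "value")

    def __post_init__(self):
        missing = [c for c in self.COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns: {missing}")
        dup = self.df.duplicated(subset=["accession_id", "trait", "environment"])
        if dup.any():
            raise ValueError("duplicate (accession, trait, environment) rows")

    def trait_names(self) -> list:
        names = self.df.apply(
            lambda r: f"{r['trait']}_{r['environment']}" if r["environment"] else r["trait"],
            axis=1,
        )
        return sorted(set(names))

    def values_for(self, trait: str, environment: Optional[str] = None) -> pd.Series:
        """Values for one trait(/environment), indexed by accession id.

        ``trait`` may also be the combined ``trait_environment`` name.
        """
        df = self.df
        if environment is not None:
            sel = df[(df["trait"] == trait) & (df["environment"] == str(environment))]
        else:
            sel = df[df["trait"] == trait]
            if sel.empty:
                combined = df["trait"].astype(str) + "_" + df["environment"].astype(str)
                sel = df[combined == trait]
            if sel["accession_id"].duplicated().any():
                raise ValueError(
                    f"trait {trait!r} measured in multiple environments; pass environment="
                )
        return pd.Series(sel["value"].values, index=sel["accession_id"].values, dtype=float)

    def environments_for(self, trait: str) -> list:
        env = self.df.loc[self.df["trait"] == trait, "environment"]
        return sorted(set(env))


@dataclass
class MarkerMapEntry:
    """One linkage-map marker, optionally anchored to a physical position."""

    marker_id: str
    linkage_group: str
    genetic_pos_cM: float
    has_alignment: bool
    chrom: Optional[str] = None
    pos_bp: Optional[int] = None

    def __post_init__(self):
        if self.has_alignment and (self.chrom is None or self.pos_bp is None):
            raise ValueError(f"marker {self.marker_id}: aligned but no physical position")


@dataclass
class QtlInterval:
    """A QTL likelihood interval in physical coordinates (1-based inclusive)."""

    chrom: str
    start_bp: int
    end_bp: int
    trait_name: str = ""
    source_study: str = ""
    pve_reported: Optional[float] = None
    crosses_centromere: bool = False

    def __post_init__(self):
        if self.end_bp < self.start_bp:
            raise ValueError(
                f"interval {self.chrom}:{self.start_bp}-{self.end_bp}: end < start"
            )

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass
class AssociationResult:
    """Per-SNP association statistics for one trait."""

    trait_name: str
    df: pd.DataFrame  # columns: snp_id, chrom, pos_bp, effect, p_value
    model_descriptor: str = ""

    COLUMNS = ("snp_id", "chrom", "pos_bp", "effect", "p_value")

    def __post_init__(self):
        missing = [c for c in self.COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"association table missing columns: {missing}")
        p = self.df["p_value"].dropna()
        if len(p) and ((p <= 0) | (p > 1)).any():
            raise ValueError("p-values must lie in (0, 1]")


# ---------------------------------------------------------------------------
# genotype I/O


def read_genotypes(path, fmt: str = "vcf") -> GenotypeMatrix:
    """Read genotypes from a VCF or an allele-count matrix TSV.

    Only biallelic SNPs are kept; multiallelic or non-SNP records are skipped
    with a warning. Stored counts always track the minor allele.
    """
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "matrix_tsv":
        return _read_matrix_tsv(path)
    raise ValueError(f"unknown genotype format: {fmt}")


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    accession_ids = list(vcf.samples)
    snp_ids, chroms, positions, columns = [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            logger.warning("skipping multiallelic/non-SNP record at %s:%d", var.CHROM, var.POS)
            continue
        # cyvcf2 gt_types: 0 HOM_REF / 1 HET / 2 UNKNOWN / 3 HOM_ALT
        gt = var.gt_types.astype(np.int16)
        col = np.where(gt == 2, MISSING, np.where(gt == 3, 2, gt))
        snp_ids.append(var.ID if var.ID and var.ID != "." else snp_id_for(var.CHROM, var.POS))
        chroms.append(var.CHROM)
        positions.append(var.POS)
        columns.append(col)
    vcf.close()
    if not columns:
        return GenotypeMatrix(accession_ids, [], np.array([], dtype=object),
                              np.array([], dtype=np.int64),
                              np.zeros((len(accession_ids), 0), dtype=np.int16))
    counts = np.column_stack(columns).astype(np.int16)
    return GenotypeMatrix.from_counts(accession_ids, snp_ids, chroms, positions, counts)


def _read_matrix_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["snp_id", "chrom", "pos_bp"]
    if list(df.columns[:3]) != required:
        raise ValueError(f"matrix TSV must start with columns {required}")
    accession_ids = list(df.columns[3:])
    counts = df[accession_ids].to_numpy(dtype=float)
    counts = np.where(np.isnan(counts), MISSING, counts).astype(np.int16)
    return GenotypeMatrix.from_counts(
        accession_ids, list(df["snp_id"]), df["chrom"].to_numpy(dtype=object),
        df["pos_bp"].to_numpy(dtype=np.int64), counts.T,
    )


def write_genotypes(gm: GenotypeMatrix, path, fmt: str = "vcf") -> None:
    """Write genotypes as a minimal VCF or a SNP-per-row allele-count TSV.

    In VCF output the ALT allele carries the stored (minor-allele) counts so
    that a read/write round trip is the identity.
    """
    path = Path(path)
    if fmt == "vcf":
        _write_vcf(gm, path)
    elif fmt == "matrix_tsv":
        _write_matrix_tsv(gm, path)
    else:
        raise ValueError(f"unknown genotype format: {fmt}")


_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def _write_vcf(gm: GenotypeMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(gm.chrom):
            length = int(gm.pos_bp[gm.chrom == chrom].max()) + 1
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(str(a) for a in gm.accession_ids) + "\n")
        for j in range(gm.n_snps):
            gts = "\t".join(_GT_CODE[int(c)] for c in gm.counts[:, j])
            fh.write(
                f"{gm.chrom[j]}\t{gm.pos_bp[j]}\t{gm.snp_ids[j]}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n"
            )


def _write_matrix_tsv(gm: GenotypeMatrix, path: Path) -> None:
    df = pd.DataFrame({"snp_id": gm.snp_ids, "chrom": gm.chrom, "pos_bp": gm.pos_bp})
    body = pd.DataFrame(
        np.where(gm.counts == MISSING, np.nan, gm.counts).T,
        columns=[str(a) for a in gm.accession_ids],
    )
    pd.concat([df, body], axis=1).to_csv(path, sep="\t", index=False, float_format="%g")


# ---------------------------------------------------------------------------
# interval I/O


def read_intervals(path, fmt: str = "bed") -> list:
    """Read QTL intervals from BED (0-based half-open) or 1-based TSV.

    Optional columns 4-6 are trait name, source study and reported PVE.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if fmt == "bed":
                start, end = start + 1, end
            elif fmt != "tsv_1based":
                raise ValueError(f"unknown interval format: {fmt}")
            if end < start:
                raise ValueError(f"{path}:{lineno}: end < start after conversion")
            trait = parts[3] if len(parts) > 3 else ""
            source = parts[4] if len(parts) > 4 else ""
            pve = float(parts[5]) if len(parts) > 5 and parts[5] not in (".", "") else None
            intervals.append(
                QtlInterval(chrom=chrom, start_bp=start, end_bp=end,
                            trait_name=trait, source_study=source, pve_reported=pve)
            )
    return intervals


def write_intervals(intervals: Iterable[QtlInterval], path, fmt: str = "bed") -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            start = iv.start_bp - 1 if fmt == "bed" else iv.start_bp
            fields = [iv.chrom, str(start), str(iv.end_bp)]
            if iv.trait_name or iv.source_study or iv.pve_reported is not None:
                fields += [iv.trait_name or ".", iv.source_study or ".",
                           "." if iv.pve_reported is None else f"{iv.pve_reported:g}"]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# phenotype, marker-map and association I/O


def read_phenotypes(path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"accession_id": str, "trait": str,
                                            "environment": str})
    df["environment"] = df["environment"].fillna("")
    return PhenotypeTable(df)


def write_phenotypes(pt: PhenotypeTable, path) -> None:
    pt.df.to_csv(path, sep="\t", index=False)


def read_marker_map(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "linkage_group": str,
                                            "chrom": str})
    entries = []
    for _, r in df.iterrows():
        aligned = bool(r["has_alignment"]) if not isinstance(r["has_alignment"], str) \
            else r["has_alignment"].strip().lower() in ("1", "true", "yes")
        entries.append(MarkerMapEntry(
            marker_id=r["marker_id"], linkage_group=r["linkage_group"],
            genetic_pos_cM=float(r["genetic_pos_cM"]), has_alignment=aligned,
            chrom=None if not aligned else r["chrom"],
            pos_bp=None if not aligned else int(r["pos_bp"]),
        ))
    return entries


def write_marker_map(entries: Sequence[MarkerMapEntry], path) -> None:
    rows = [{
        "marker_id": e.marker_id, "linkage_group": e.linkage_group,
        "genetic_pos_cM": e.genetic_pos_cM, "has_alignment": int(e.has_alignment),
        "chrom": e.chrom if e.has_alignment else "",
        "pos_bp": e.pos_bp if e.has_alignment else "",
    } for e in entries]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_association(result: AssociationResult, path) -> None:
    """Tab-delimited association output; p-values keep >= 6 significant digits."""
    df = result.df.copy()
    df["trait"] = result.trait_name
    df = df[["snp_id", "chrom", "pos_bp", "trait", "effect", "p_value"]]
    df["p_value"] = df["p_value"].map(
        lambda p: "" if pd.isna(p) else f"{p:.5e}"
    )
    df["effect"] = df["effect"].map(lambda b: "" if pd.isna(b) else f"{b:.6g}")
    df.to_csv(path, sep="\t", index=False)


def read_association(path) -> AssociationResult:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    traits = df["trait"].dropna().unique()
    trait = traits[0] if len(traits) else ""
    df = df.rename(columns={"trait": "_trait"})
    out = df[["snp_id", "chrom", "pos_bp", "effect", "p_value"]].copy()
    return AssociationResult(trait_name=str(trait), df=out)
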
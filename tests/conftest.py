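import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from seedgwas.association import MlmConfig, kinship_matrix, mlm_scan
from seedgwas.simulate import (SimulationConfig, sap_like_config,
                               simulate_phenotypes, simulate_population)
from seedgwas.structure import compute_pca


@pytest.fixture(scope="session")
def small_panel():
    """A small structured panel: 3 subpopulations, 2 chromosomes, 600 SNPs."""
    cfg = SimulationConfig(n_accessions=150, n_snps=600, n_chromosomes=2,
                           chrom_length_bp=6_000_000, ld_block_len_bp=150_000,
                           fst_like_divergence=0.2, n_subpops=3, rng_seed=42)
    gm, truth = simulate_population(cfg)
    return cfg, gm, truth


@pytest.fixture(scope="session")
def sap_panel_scanned():
    """The full panel emulation with planted loci, scanned in one environment.

    Session-scoped: several tests reuse this single simulate -> scan run.
    """
    cfg = sap_like_config(rng_seed=1)
    gm, truth = simulate_population(cfg)
    pt = simulate_phenotypes(gm, truth, cfg)
    K = kinship_matrix(gm)
    struct = compute_pca(gm, n_pcs=2)
    assoc = mlm_scan(gm, pt, K, struct, MlmConfig(), "sim_trait", "env1")
    return cfg, gm, truth, pt, K, struct, assoc


def brute_force_hotspots(assoc, gm, cfg):
    """Independent quadratic reimplementation of the hotspot rule.

    Enumerates every seed and every minor pair, recomputes r2 directly from
    the genotype columns, and merges connected components; used as the oracle
    against detect_hotspots.
    """
    df = assoc.df.dropna(subset=["p_value"]).reset_index(drop=True)
    col = {s: np.asarray(gm.column(s), dtype=float) for s in df["snp_id"]}

    def r2(x, y):
        ok = (x >= 0) & (y >= 0)
        x, y = x[ok], y[ok]
        if len(x) < 2 or x.std() == 0 or y.std() == 0:
            return np.nan
        return float(np.corrcoef(x, y)[0, 1]) ** 2

    seeds = df[df["p_value"] <= cfg.seed_threshold]
    minors = df[(df["p_value"] > cfg.seed_threshold) & (df["p_value"] <= cfg.minor_lower)]
    protos = []
    for _, s in seeds.iterrows():
        if s["snp_id"] not in gm.snp_ids:
            continue
        x = col[s["snp_id"]]
        called = x[x >= 0]
        if called.size == 0 or called.min() == called.max():
            continue
        linked = []
        for _, m in minors.iterrows():
            if m["chrom"] != s["chrom"]:
                continue
            if abs(m["pos_bp"] - s["pos_bp"]) > cfg.max_link_dist_bp:
                continue
            if m["snp_id"] not in gm.snp_ids:
                continue
            v = r2(x, col[m["snp_id"]])
            if not np.isnan(v) and v >= cfg.link_threshold:
                linked.append(m["snp_id"])
        if len(linked) >= cfg.min_support:
            members = {s["snp_id"]} | set(linked)
            pos = [int(s["pos_bp"])] + [int(minors.set_index("snp_id").loc[x2, "pos_bp"])
                                        for x2 in linked]
            protos.append({"seeds": {s["snp_id"]}, "minors": set(linked),
                           "chrom": s["chrom"], "lo": min(pos), "hi": max(pos),
                           "members": members})
    if cfg.merge_overlapping:
        changed = True
        while changed:
            changed = False
            for i in range(len(protos)):
                for j in range(i + 1, len(protos)):
                    a, b = protos[i], protos[j]
                    if a["chrom"] != b["chrom"]:
                        continue
                    share = a["members"] & b["members"]
                    overlap = max(a["lo"], b["lo"]) <= min(a["hi"], b["hi"])
                    if share or overlap:
                        a["seeds"] |= b["seeds"]
                        a["minors"] |= b["minors"]
                        a["members"] |= b["members"]
                        a["lo"] = min(a["lo"], b["lo"])
                        a["hi"] = max(a["hi"], b["hi"])
                        del protos[j]
                        changed = True
                        break
                if changed:
                    break
    return sorted(
        (str(p["chrom"]), p["lo"], p["hi"], frozenset(p["seeds"]), frozenset(p["minors"]))
        for p in protos
    )
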
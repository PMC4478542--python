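#!/usr/bin/env python
"""Population structure and trait differentiation.

PCA on the simulated panel, K-means (k=3) on the first two components,
agreement with the planted ancestry groups, group-pair Welch t-tests of the
trait in each environment, the allele-frequency spectrum of the strongest
planted locus by group, and between-environment trait correlations.
"""

from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from seedgwas import io as gio
from seedgwas.structure import (allele_freq_by_group, compute_pca,
                                group_trait_ttests, kmeans_groups,
                                repeatability_across_environments,
                                trait_correlation)

SEED = 1
ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "panel"
RESULTS = ROOT / "results"


def main():
    gm = gio.read_genotypes(SCRATCH / "genotypes.tsv", "matrix_tsv")
    pt = gio.read_phenotypes(RESULTS / "phenotypes.tsv")
    truth_labels = np.array([
        int(x) for x in (RESULTS / "truth.tsv").read_text()
        .splitlines()[0].split("\t")[1].split(",")])

    res = compute_pca(gm, n_pcs=2)
    labels = kmeans_groups(res.pc_scores, k=3, rng_seed=SEED)
    ari = adjusted_rand_score(truth_labels, labels)
    print(f"PC1/PC2 variance explained: {np.round(res.variance_explained, 4)}")
    print(f"K-means (k=3) vs planted groups: adjusted Rand = {ari:.3f}")

    scores = pd.DataFrame(res.pc_scores, columns=["PC1", "PC2"])
    scores.insert(0, "accession_id", res.accession_ids)
    scores["group"] = labels
    scores.to_csv(RESULTS / "structure_pcs_groups.tsv", sep="\t", index=False)

    # Welch t-tests of the trait between groups, per environment
    rows = []
    for env in pt.environments_for("seed_size"):
        diff = group_trait_ttests(pt, labels, res.accession_ids,
                                  "seed_size", env)
        for (g1, g2), p in diff.p_values.items():
            rows.append({"environment": env, "group_1": g1, "group_2": g2,
                         "p_value": p, "significant_1e-4": diff.significant[(g1, g2)]})
    pd.DataFrame(rows).to_csv(RESULTS / "group_differentiation.tsv",
                              sep="\t", index=False)
    print("group differentiation written (smallest p = "
          f"{min(r['p_value'] for r in rows):.3g})")

    # allele frequency by group at the strongest planted locus
    causal = [ln.split("\t")[1] for ln in (RESULTS / "truth.tsv").read_text()
              .splitlines() if ln.startswith("causal")]
    freqs = allele_freq_by_group(gm, labels, causal[0])
    print(f"allele frequency of {causal[0]} by group: "
          + ", ".join(f"group {g}: {f:.3f}" for g, f in freqs.items()))

    # trait correlations between environments + repeatability
    envs = pt.environments_for("seed_size")
    rows = []
    for i, ex in enumerate(envs):
        for ey in envs[i + 1:]:
            tc = trait_correlation(pt, "seed_size", "seed_size", ex, ey)
            rows.append({"env_x": ex, "env_y": ey, "pearson_r": tc.pearson_r,
                         "ols_slope": tc.ols_slope_beta, "n": tc.n_pairs})
    corr = pd.DataFrame(rows)
    corr.to_csv(RESULTS / "trait_correlations.tsv", sep="\t", index=False)
    H = repeatability_across_environments(pt, "seed_size")
    print(f"between-environment r: {np.round(corr['pearson_r'].values, 3)}; "
          f"repeatability H = {H.repeatability_H:.3f}")


if __name__ == "__main__":
    main()
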
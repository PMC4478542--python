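import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from seedgwas.io import GenotypeMatrix, PhenotypeTable
from seedgwas.simulate import (SimulationConfig, simulate_phenotypes,
                               simulate_population)
from seedgwas.structure import (allele_freq_by_group, compute_pca,
                                group_trait_ttests, kmeans_groups,
                                repeatability_across_environments,
                                trait_correlation)


def _pheno(values_by_trait_env):
    rows = []
    for (trait, env), series in values_by_trait_env.items():
        for acc, v in series.items():
            rows.append({"accession_id": acc, "trait": trait,
                         "environment": env, "value": v})
    return PhenotypeTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# PCA


def test_pca_separates_two_clusters_of_clones():
    counts = np.vstack([np.tile([0, 0, 2, 2, 0, 2], (10, 1)),
                        np.tile([2, 2, 0, 0, 2, 0], (10, 1))]).astype(np.int16)
    gm = GenotypeMatrix([f"a{i}" for i in range(20)],
                        [f"S1_{j}" for j in range(100, 700, 100)],
                        ["Sb01"] * 6, list(range(100, 700, 100)), counts)
    res = compute_pca(gm, n_pcs=1)
    s = res.pc_scores[:, 0]
    assert (s[:10] > 0).all() != (s[10:] > 0).all()  # PC1 splits the clusters
    assert res.variance_explained[0] == pytest.approx(1.0, abs=1e-10)


def test_pca_accession_permutation_equivariance(small_panel):
    _, gm, _ = small_panel
    res = compute_pca(gm, n_pcs=2)
    rng = np.random.default_rng(0)
    perm = rng.permutation(gm.n_accessions)
    gm_p = GenotypeMatrix([gm.accession_ids[i] for i in perm], list(gm.snp_ids),
                          gm.chrom.copy(), gm.pos_bp.copy(),
                          gm.counts[perm].copy())
    res_p = compute_pca(gm_p, n_pcs=2)
    np.testing.assert_allclose(res_p.pc_scores, res.pc_scores[perm],
                               rtol=1e-8, atol=1e-8)


def test_pca_reproduces_direct_eigendecomposition(small_panel):
    """Leading eigenvalues of the standardized genotype covariance from the
    SVD path match a dense eigendecomposition oracle."""
    _, gm, _ = small_panel
    res = compute_pca(gm, n_pcs=3)
    from seedgwas.structure import _imputed_standardized
    Z, _ = _imputed_standardized(gm)
    evals = np.linalg.eigvalsh(Z @ Z.T)[::-1]
    score_norms = (res.pc_scores ** 2).sum(axis=0)
    np.testing.assert_allclose(score_norms, evals[:3], rtol=1e-8)
    assert np.all(np.diff(res.variance_explained) <= 1e-12)


def test_pca_rank_error():
    counts = np.array([[0, 0], [2, 2], [0, 0]], dtype=np.int16)
    gm = GenotypeMatrix(["a", "b", "c"], ["S1_1", "S1_2"], ["Sb01", "Sb01"],
                        [1, 2], counts)
    with pytest.raises(ValueError, match="rank"):
        compute_pca(gm, n_pcs=3)


# ---------------------------------------------------------------------------
# K-means


def test_kmeans_recovers_separated_blobs():
    rng = np.random.default_rng(0)
    blobs = np.vstack([rng.normal([0, 0], 0.3, (30, 2)),
                       rng.normal([8, 0], 0.3, (30, 2)),
                       rng.normal([4, 7], 0.3, (30, 2))])
    truth = np.repeat([1, 2, 3], 30)
    labels = kmeans_groups(blobs, k=3, rng_seed=0)
    assert adjusted_rand_score(truth, labels) == 1.0


def test_kmeans_k1_and_duplicates():
    pts = np.array([[1.0, 1.0]] * 5 + [[2.0, 2.0]] * 5)
    assert set(kmeans_groups(pts, k=1)) == {1}
    l1 = kmeans_groups(pts, k=2, rng_seed=0, n_restarts=5)
    l2 = kmeans_groups(pts, k=2, rng_seed=1, n_restarts=5)
    np.testing.assert_array_equal(l1, l2)  # stable under restarts


def test_planted_subpopulations_recovered():
    # strongly diverged subpopulations: the first two PCs suffice for K-means
    cfg = SimulationConfig(n_accessions=150, n_snps=800, n_chromosomes=2,
                           chrom_length_bp=6_000_000, fst_like_divergence=0.5,
                           n_subpops=3, rng_seed=7)
    gm, truth = simulate_population(cfg)
    res = compute_pca(gm, n_pcs=2)
    labels = kmeans_groups(res.pc_scores, k=3, rng_seed=0)
    assert adjusted_rand_score(truth.subpop_labels, labels) > 0.95


# ---------------------------------------------------------------------------
# group t-tests


def test_ttest_identical_groups_p_one():
    acc = [f"a{i}" for i in range(8)]
    pt = _pheno({("w", ""): dict(zip(acc, [1.0, 1.0, 1.0, 1.0] * 2))})
    res = group_trait_ttests(pt, [1, 1, 1, 1, 2, 2, 2, 2], acc, "w")
    assert res.p(1, 2) == 1.0
    assert not res.significant[(1, 2)]


def test_ttest_separated_groups_flagged():
    rng = np.random.default_rng(1)
    acc = [f"a{i}" for i in range(100)]
    vals = np.concatenate([rng.normal(0, 1, 50), rng.normal(5, 1, 50)])
    pt = _pheno({("w", ""): dict(zip(acc, vals))})
    labels = [1] * 50 + [2] * 50
    res = group_trait_ttests(pt, labels, acc, "w")
    assert res.p(1, 2) < 1e-4
    assert res.significant[(1, 2)]


def test_ttest_small_group_reported_missing():
    acc = ["a1", "a2", "a3"]
    pt = _pheno({("w", ""): {"a1": 1.0, "a2": 2.0, "a3": 3.0}})
    res = group_trait_ttests(pt, [1, 1, 2], acc, "w")
    assert np.isnan(res.p(1, 2))


def test_ttest_matches_permutation_oracle():
    rng = np.random.default_rng(5)
    x = rng.normal(0.0, 1.0, 10)
    y = rng.normal(0.8, 1.0, 10)
    acc = [f"a{i}" for i in range(20)]
    pt = _pheno({("w", ""): dict(zip(acc, np.concatenate([x, y])))})
    res = group_trait_ttests(pt, [1] * 10 + [2] * 10, acc, "w")
    # permutation oracle on the Welch statistic
    obs = abs(stats.ttest_ind(x, y, equal_var=False).statistic)
    pooled = np.concatenate([x, y])
    n_perm, hits = 4000, 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        t = abs(stats.ttest_ind(perm[:10], perm[10:], equal_var=False).statistic)
        hits += t >= obs
    p_perm = (hits + 1) / (n_perm + 1)
    mc_se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
    assert res.p(1, 2) == pytest.approx(p_perm, abs=max(0.02, 4 * mc_se))


def test_group_pattern_emulates_stratified_seed_width():
    """A synthetic regime where group III seeds are much wider than group I
    puts the I-vs-III cell at the smallest p of the matrix."""
    rng = np.random.default_rng(3)
    acc = [f"a{i}" for i in range(120)]
    labels = np.repeat([1, 2, 3], 40)
    means = {1: 2.0, 2: 2.15, 3: 2.6}
    vals = rng.normal([means[g] for g in labels], 0.25)
    pt = _pheno({("seed_width", "2008"): dict(zip(acc, vals))})
    res = group_trait_ttests(pt, labels, acc, "seed_width", "2008")
    p13 = res.p(1, 3)
    assert p13 == min(res.p_values.values())
    assert res.significant[(1, 3)]


# ---------------------------------------------------------------------------
# allele frequencies by group


def test_allele_freq_direct_counts():
    counts = np.array([[2], [2], [0], [0], [0], [0], [0], [0]], dtype=np.int16)
    gm = GenotypeMatrix([f"a{i}" for i in range(8)], ["S1_10"], ["Sb01"], [10],
                        counts)
    freqs = allele_freq_by_group(gm, [1, 1, 1, 1, 1, 2, 2, 2], "S1_10")
    assert freqs[1] == pytest.approx(0.4)   # counts [2,2,0,0,0] -> 4/10
    assert freqs[2] == 0.0                  # all-homozygous-major group


def test_allele_freq_missing_group():
    counts = np.array([[2], [-1], [-1]], dtype=np.int16)
    gm = GenotypeMatrix(["a", "b", "c"], ["S1_10"], ["Sb01"], [10], counts)
    freqs = allele_freq_by_group(gm, [1, 2, 2], "S1_10")
    assert np.isnan(freqs[2])


def test_allele_freq_group_stratified_recovery():
    """A SNP planted with group frequencies (0.3, 0.12, 0.05) is recovered
    within binomial sampling error."""
    rng = np.random.default_rng(11)
    sizes, target = [120, 120, 120], [0.30, 0.12, 0.05]
    col = np.concatenate([
        2 * (rng.random(s) < p).astype(np.int16) for s, p in zip(sizes, target)
    ])[:, None]
    gm = GenotypeMatrix([f"a{i}" for i in range(360)], ["S1_10"], ["Sb01"],
                        [10], col)
    labels = np.repeat([1, 2, 3], 120)
    freqs = allele_freq_by_group(gm, labels, "S1_10")
    for g, p in zip((1, 2, 3), target):
        se = np.sqrt(p * (1 - p) / 120)
        assert abs(freqs[g] - p) < 4 * se + 1e-9


# ---------------------------------------------------------------------------
# correlations and repeatability


def test_trait_correlation_exact_cases():
    acc = [f"a{i}" for i in range(10)]
    x = dict(zip(acc, np.arange(10.0)))
    pt = _pheno({("x", ""): x, ("y", ""): {a: 2 * v for a, v in x.items()}})
    tc = trait_correlation(pt, "x", "y")
    assert tc.pearson_r == pytest.approx(1.0)
    assert tc.ols_slope_beta == pytest.approx(2.0)
    pt2 = _pheno({("x", ""): x, ("y", ""): x})
    tc2 = trait_correlation(pt2, "x", "y")
    assert (tc2.pearson_r, tc2.ols_slope_beta) == (pytest.approx(1.0), pytest.approx(1.0))


def test_trait_correlation_noisy_slope():
    rng = np.random.default_rng(8)
    acc = [f"a{i}" for i in range(1000)]
    x = rng.normal(0, 1, 1000)
    y = -0.5 * x + rng.normal(0, 1, 1000)
    pt = _pheno({("x", ""): dict(zip(acc, x)), ("y", ""): dict(zip(acc, y))})
    tc = trait_correlation(pt, "x", "y")
    r_expected = -0.5 / np.sqrt(0.25 + 1.0)
    assert tc.ols_slope_beta == pytest.approx(-0.5, abs=0.1)
    assert tc.pearson_r == pytest.approx(r_expected, abs=0.08)
    assert tc.n_pairs == 1000


def test_trait_correlation_constant_x_undefined_slope():
    acc = ["a", "b", "c", "d"]
    pt = _pheno({("x", ""): dict.fromkeys(acc, 1.0),
                 ("y", ""): dict(zip(acc, [1.0, 2.0, 3.0, 4.0]))})
    tc = trait_correlation(pt, "x", "y")
    assert np.isnan(tc.ols_slope_beta)


def test_repeatability_identical_environments_H_one():
    acc = [f"a{i}" for i in range(20)]
    vals = dict(zip(acc, np.linspace(1, 5, 20)))
    pt = _pheno({("m", "2008"): vals, ("m", "2009"): vals, ("m", "2010"): vals})
    est = repeatability_across_environments(pt, "m")
    assert est.repeatability_H == pytest.approx(1.0)


def test_repeatability_pure_noise_near_zero():
    rng = np.random.default_rng(2)
    hs = []
    for rep in range(20):
        acc = [f"a{i}" for i in range(300)]
        pt = _pheno({("m", str(y)): dict(zip(acc, rng.normal(0, 1, 300)))
                     for y in (2008, 2009, 2010)})
        hs.append(repeatability_across_environments(pt, "m").repeatability_H)
    assert np.mean(hs) <= 0.05


def test_repeatability_shift_and_scale_invariant():
    rng = np.random.default_rng(4)
    acc = [f"a{i}" for i in range(100)]
    g = rng.normal(0, 1, 100)
    env = {str(y): dict(zip(acc, g + rng.normal(0, 1, 100))) for y in (1, 2, 3)}
    pt = _pheno({("m", y): v for y, v in env.items()})
    h0 = repeatability_across_environments(pt, "m").repeatability_H
    pt2 = _pheno({("m", y): {a: 7.0 + 3.0 * v for a, v in d.items()}
                  for y, d in env.items()})
    h1 = repeatability_across_environments(pt2, "m").repeatability_H
    assert h1 == pytest.approx(h0, abs=1e-12)


def test_repeatability_single_environment_error():
    acc = ["a", "b", "c"]
    pt = _pheno({("m", "2008"): dict(zip(acc, [1.0, 2.0, 3.0]))})
    with pytest.raises(ValueError, match="2 environments"):
        repeatability_across_environments(pt, "m")


def test_repeatability_recovers_simulated_target():
    """The 0.31-heritability regime: simulated multi-environment seed mass
    recovers H within +-0.05 over 20 replicates."""
    hs = []
    for rep in range(20):
        cfg = SimulationConfig(n_accessions=354, n_snps=300, n_chromosomes=1,
                               chrom_length_bp=3_000_000, rng_seed=100 + rep,
                               target_h2=0.31, n_environments=3,
                               polygenic_var=1.0, n_subpops=1,
                               fst_like_divergence=0.0)
        gm, truth = simulate_population(cfg)
        pt = simulate_phenotypes(gm, truth, cfg, trait_name="seed_mass")
        hs.append(repeatability_across_environments(pt, "seed_mass").repeatability_H)
    assert abs(np.mean(hs) - 0.31) <= 0.05
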
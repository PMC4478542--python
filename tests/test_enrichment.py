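import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from seedgwas.enrichment import (ContingencyTable, OrthologPairSet,
                                 cross_taxa_correspondence_test, fisher_exact,
                                 qtl_gwas_overlap_test,
                                 qtl_qtl_correspondence_test,
                                 read_ortholog_pairs, uniformized_p,
                                 write_ortholog_pairs)
from seedgwas.io import AssociationResult, QtlInterval
from seedgwas.simulate import simulate_ortholog_map


def exact_oracle(a, b, c, d):
    """Full fixed-margin enumeration with exact rational arithmetic."""
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = {k: math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)}
    total = math.comb(r1 + r2, c1)
    one = Fraction(sum(w for k, w in weights.items() if k >= a), total)
    two = Fraction(sum(w for w in weights.values() if w <= weights[a]), total)
    return float(one), float(two)


@pytest.mark.parametrize("table, expected_one", [
    ((5, 0, 0, 5), 1 / 252),      # 1 / C(10,5)
    ((2, 1, 1, 2), 0.5),          # P(A>=2) = 9/20 + 1/20
    ((1, 1, 1, 1), 5 / 6),
    ((8, 2, 12, 78), 2.3782749640379137e-05),
])
def test_fisher_exact_known_values(table, expected_one):
    res = fisher_exact(ContingencyTable(*table))
    assert res.p_one_sided == pytest.approx(expected_one, rel=1e-12)


def test_fisher_degenerate_margins():
    res = fisher_exact(ContingencyTable(0, 0, 0, 0))
    assert res.degenerate and res.p_one_sided == 1.0 and res.p_two_sided == 1.0
    res = fisher_exact(ContingencyTable(0, 0, 3, 4))
    assert res.degenerate


def test_odds_ratio_conventions():
    assert fisher_exact(ContingencyTable(2, 1, 1, 2)).odds_ratio == pytest.approx(4.0)
    assert math.isinf(fisher_exact(ContingencyTable(3, 0, 1, 3)).odds_ratio)
    assert math.isnan(fisher_exact(ContingencyTable(0, 0, 1, 3)).odds_ratio)


@settings(max_examples=200, deadline=None)
@given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30),
       st.integers(0, 30))
def test_fisher_matches_enumeration_and_scipy(a, b, c, d):
    res = fisher_exact(ContingencyTable(a, b, c, d))
    if res.degenerate:
        return
    one, two = exact_oracle(a, b, c, d)
    assert abs(res.p_one_sided - one) < 1e-12
    assert abs(res.p_two_sided - two) < 1e-12
    # independent library cross-checks
    assert res.p_one_sided == pytest.approx(
        stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1], rel=1e-9)
    assert res.p_two_sided == pytest.approx(
        stats.fisher_exact([[a, b], [c, d]])[1], rel=1e-9)


@settings(max_examples=100, deadline=None)
@given(st.integers(0, 40), st.integers(0, 40), st.integers(0, 40),
       st.integers(0, 40))
def test_one_sided_complement_identity(a, b, c, d):
    """P(A >= a) must equal 1 - P(A <= a-1), computed independently."""
    t = ContingencyTable(a, b, c, d)
    res = fisher_exact(t)
    if res.degenerate:
        return
    r1, r2, c1 = a + b, c + d, a + c
    lo = max(0, c1 - r2)
    total = math.comb(r1 + r2, c1)
    below = Fraction(sum(math.comb(r1, k) * math.comb(r2, c1 - k)
                         for k in range(lo, a)), total)
    assert abs(res.p_one_sided - float(1 - below)) < 1e-12


# ---------------------------------------------------------------------------
# within-genome overlap


def _assoc(snp_pos, sig_mask, chrom="Sb01"):
    df = pd.DataFrame({
        "snp_id": [f"S1_{p}" for p in snp_pos], "chrom": chrom,
        "pos_bp": snp_pos, "effect": 0.1,
        "p_value": [1e-6 if s else 0.5 for s in sig_mask],
    })
    return AssociationResult(trait_name="t", df=df)


def test_overlap_test_builds_documented_table():
    # 100 SNPs, 20 inside intervals, 10 significant of which 8 inside
    pos = list(range(1000, 101000, 1000))
    inside = set(pos[:20])
    sig = set(pos[:8]) | set(pos[50:52])
    assoc = _assoc(pos, [p in sig for p in pos])
    qtl = [QtlInterval(chrom="Sb01", start_bp=1, end_bp=20000)]
    res = qtl_gwas_overlap_test(assoc, qtl, sig_threshold=1e-5)
    assert res.table.as_tuple() == (8, 2, 12, 78)
    one, two = exact_oracle(8, 2, 12, 78)
    assert res.p_one_sided == pytest.approx(one, rel=1e-12)


def test_overlap_invariant_to_splitting_intervals():
    pos = list(range(1000, 51000, 1000))
    sig = [i % 7 == 0 for i in range(len(pos))]
    assoc = _assoc(pos, sig)
    whole = [QtlInterval(chrom="Sb01", start_bp=1, end_bp=30000)]
    split = [QtlInterval(chrom="Sb01", start_bp=1, end_bp=15000),
             QtlInterval(chrom="Sb01", start_bp=15001, end_bp=30000)]
    r1 = qtl_gwas_overlap_test(assoc, whole)
    r2 = qtl_gwas_overlap_test(assoc, split)
    assert r1.table.as_tuple() == r2.table.as_tuple()
    assert r1.p_one_sided == r2.p_one_sided


def test_overlap_positive_control_enrichment():
    """Significant SNPs planted inside intervals covering 10% of the genome."""
    rng = np.random.default_rng(0)
    pos = np.sort(rng.choice(np.arange(1, 1_000_000), size=400, replace=False))
    qtl = [QtlInterval(chrom="Sb01", start_bp=1, end_bp=100_000)]
    sig = [(p <= 100_000) and (rng.random() < 0.5) for p in pos]
    if sum(sig) < 3:  # ensure a handful of significant SNPs
        sig[0] = sig[1] = sig[2] = True
    assoc = _assoc(list(pos), sig)
    res = qtl_gwas_overlap_test(assoc, qtl)
    assert res.p_one_sided < 0.01


def test_overlap_null_calibration_uniformized():
    """Under random placement of significant SNPs the uniformized one-sided
    p-value is U(0,1) (KS test), and the raw discrete p is conservative."""
    rng = np.random.default_rng(7)
    pos = np.arange(1000, 201000, 1000)
    qtl = [QtlInterval(chrom="Sb01", start_bp=1, end_bp=60_000)]
    u_vals, raw = [], []
    for _ in range(500):
        sig_idx = rng.choice(len(pos), size=20, replace=False)
        mask = np.zeros(len(pos), dtype=bool)
        mask[sig_idx] = True
        res = qtl_gwas_overlap_test(_assoc(list(pos), list(mask)), qtl)
        u_vals.append(uniformized_p(res.table, rng))
        raw.append(res.p_one_sided)
    ks = stats.kstest(u_vals, "uniform")
    assert ks.pvalue > 0.01
    # conservative: empirical CDF of the raw p never exceeds uniform + KS band
    raw = np.sort(raw)
    ecdf = np.arange(1, len(raw) + 1) / len(raw)
    band = 1.63 / math.sqrt(len(raw))  # alpha=0.01 one-sided KS band
    assert np.all(ecdf <= raw + band)


# ---------------------------------------------------------------------------
# cross-taxa tests


def _ortholog_frame(rows):
    return OrthologPairSet(pd.DataFrame(rows, columns=list(OrthologPairSet.COLUMNS)))


def test_cross_taxa_small_enumeration():
    rows = [
        ("a1", "Sb04", 100, 200, "b1", "Os02", 100, 200, "+"),     # in both
        ("a2", "Sb04", 10_000, 10_100, "b2", "Os02", 900, 1000, "+"),  # A only
        ("a3", "Sb04", 50_000, 50_100, "b3", "Os02", 300, 400, "+"),   # B only
        ("a4", "Sb04", 60_000, 60_100, "b4", "Os02", 9000, 9100, "+"),  # neither
    ]
    orth = _ortholog_frame(rows)
    hotspot = QtlInterval(chrom="Sb04", start_bp=1, end_bp=20_000)
    qtl_b = [QtlInterval(chrom="Os02", start_bp=1, end_bp=500)]
    res = cross_taxa_correspondence_test(hotspot, qtl_b, orth, ("Sb04", "Os02"))
    assert res.table.as_tuple() == (1, 1, 1, 1)
    assert res.p_one_sided == pytest.approx(5 / 6, rel=1e-12)


def test_cross_taxa_empty_universe_is_error():
    orth = _ortholog_frame([("a1", "Sb04", 1, 10, "b1", "Os02", 1, 10, "+")])
    with pytest.raises(ValueError, match="no collinear orthologs"):
        cross_taxa_correspondence_test(
            QtlInterval(chrom="Sb07", start_bp=1, end_bp=10),
            [], orth, ("Sb07", "Os08"))


def test_cross_taxa_planted_correspondence_positive_control():
    layout_a = {"Sb04": 10_000_000}
    layout_b = {"Os02": 8_000_000}
    orth = simulate_ortholog_map(
        400, layout_a, layout_b, loss_rate=0.1, rng_seed=5,
        planted_blocks=[(("Sb04", 4_000_000, 4_500_000),
                         ("Os02", 3_000_000, 3_400_000), 40)])
    hotspot = QtlInterval(chrom="Sb04", start_bp=4_000_000, end_bp=4_500_000)
    qtl_b = [QtlInterval(chrom="Os02", start_bp=3_000_000, end_bp=3_400_000)]
    res = cross_taxa_correspondence_test(hotspot, qtl_b, orth, ("Sb04", "Os02"))
    assert res.p_one_sided < 0.01


def test_cross_taxa_shuffled_positions_null():
    rng = np.random.default_rng(13)
    layout_a = {"Sb04": 10_000_000}
    layout_b = {"Os02": 8_000_000}
    hotspot = QtlInterval(chrom="Sb04", start_bp=2_000_000, end_bp=3_000_000)
    qtl_b = [QtlInterval(chrom="Os02", start_bp=1_000_000, end_bp=2_000_000)]
    u_vals = []
    for rep in range(200):
        orth = simulate_ortholog_map(150, layout_a, layout_b, rng_seed=rep)
        df = orth.df.copy()
        perm = rng.permutation(len(df))
        df[["gene_b", "chrom_b", "start_b", "end_b"]] = \
            df[["gene_b", "chrom_b", "start_b", "end_b"]].iloc[perm].values
        res = cross_taxa_correspondence_test(hotspot, qtl_b,
                                             OrthologPairSet(df), ("Sb04", "Os02"))
        u_vals.append(uniformized_p(res.table, rng))
    assert stats.kstest(u_vals, "uniform").pvalue > 0.01


def test_qtl_qtl_identity_map_perfect_correspondence():
    rows = []
    for i in range(60):
        s = 100_000 * (i + 1)
        rows.append((f"a{i}", "Sb01", s, s + 3000, f"b{i}", "Os01", s, s + 3000, "+"))
    orth = _ortholog_frame(rows)
    qtl = [QtlInterval(chrom="Sb01", start_bp=1, end_bp=1_000_000),
           QtlInterval(chrom="Sb01", start_bp=2_000_000, end_bp=2_500_000)]
    qtl_b = [QtlInterval(chrom="Os01", start_bp=1, end_bp=1_000_000),
             QtlInterval(chrom="Os01", start_bp=2_000_000, end_bp=2_500_000)]
    res = qtl_qtl_correspondence_test(qtl, qtl_b, orth)
    assert res.table.a == 2 and res.table.b == 0
    assert res.p_one_sided < 1.0


def test_qtl_qtl_no_b_coverage_degenerate():
    rows = [(f"a{i}", "Sb01", 1000 * i + 1, 1000 * i + 500,
             f"b{i}", "Os01", 1000 * i + 1, 1000 * i + 500, "+")
            for i in range(1, 30)]
    orth = _ortholog_frame(rows)
    qtl = [QtlInterval(chrom="Sb01", start_bp=1, end_bp=10_000)]
    res = qtl_qtl_correspondence_test(qtl, [], orth)
    assert res.degenerate and res.p_one_sided == 1.0
    assert res.table.a == 0


def test_qtl_qtl_planted_seven_of_nine():
    """Seven of nine A intervals projected inside B intervals vs ~20% chance
    coverage rejects the null at 0.05."""
    rng = np.random.default_rng(21)
    rows = []
    gid = 0
    b_iv = []
    a_iv = []
    # 9 A intervals; the first 7 project into dedicated B intervals
    for i in range(9):
        a_start = 2_000_000 * i + 1
        a_iv.append(QtlInterval(chrom="Sb01", start_bp=a_start,
                                end_bp=a_start + 500_000))
        hit = i < 7
        b_start = 2_000_000 * i + 1 if hit else 40_000_000 + 2_000_000 * i
        if hit:
            b_iv.append(QtlInterval(chrom="Os01", start_bp=b_start,
                                    end_bp=b_start + 500_000))
        for j in range(6):
            gid += 1
            pa = a_start + 80_000 * j
            pb = b_start + 80_000 * j
            rows.append((f"a{gid}", "Sb01", pa, pa + 3000,
                         f"b{gid}", "Os01", pb, pb + 3000, "+"))
    # background ortholog genes giving ~20% chance coverage on Os01
    total_b_len = sum(iv2.length_bp for iv2 in b_iv)
    span = int(total_b_len / 0.2)
    for j in range(300):
        gid += 1
        pa = 60_000_000 + 10_000 * j
        pb = int(rng.integers(1, span))
        rows.append((f"a{gid}", "Sb01", pa, pa + 3000,
                     f"b{gid}", "Os01", pb, pb + 3000, "+"))
    orth = _ortholog_frame(rows)
    res = qtl_qtl_correspondence_test(a_iv, b_iv, orth)
    assert res.table.a == 7 and res.table.b == 2
    assert res.p_one_sided < 0.05


def test_ortholog_round_trip(tmp_path):
    orth = simulate_ortholog_map(100, {"Sb01": 5_000_000}, {"Os01": 4_000_000},
                                 inversion_rate=0.3, loss_rate=0.2, rng_seed=3)
    path = tmp_path / "orth.tsv"
    write_ortholog_pairs(orth, path)
    back = read_ortholog_pairs(path)
    pd.testing.assert_frame_equal(back.df, orth.df)
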
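"""Weir-Cockerham FST against an independent formula transcription,
windowed scans, nucleotide diversity, and marker-class comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pangenpop.differentiation import (band_of, compare_marker_classes,
                                       fst_scan, gene_flank_fst,
                                       genome_weighted_fst, site_fst,
                                       svs_as_matrix, windowed_fst_pi)
from pangenpop.io_filters import (GeneModel, GenomeLayout, GroupDesign,
                                  SnpMatrix, SvRecord)
from pangenpop.synthetic_data import simulate_balding_nichols

from conftest import two_group_design


# ---------------------------------------------------------------------------
# independent transcription of the 1984 variance-component formulas
# ---------------------------------------------------------------------------

def wc_oracle(n1, n2, p1, p2, h1, h2):
    """Separate, scalar transcription of the two-population estimator."""
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    ssq = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = nbar / nc * (ssq - 1 / (nbar - 1)
                     * (pbar * (1 - pbar) - (r - 1) / r * ssq - hbar / 4))
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * ssq
                             - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


def _geno(counts):
    """Dosage vector from (n_hom_ref, n_het, n_hom_alt)."""
    return np.array([0] * counts[0] + [1] * counts[1] + [2] * counts[2],
                    dtype=np.int8)


def test_fixed_difference_is_one():
    r = site_fst(_geno((0, 0, 10)), _geno((10, 0, 0)))
    assert r.fst == pytest.approx(1.0)


def test_no_differentiation_non_positive_mean():
    """Identical genotype composition in both groups: the estimate is
    <= 0 per site and ~0 in expectation over random sites."""
    r = site_fst(_geno((5, 10, 5)), _geno((5, 10, 5)))
    assert r.fst is not None and r.fst <= 0
    rng = np.random.default_rng(0)
    vals = []
    for _ in range(500):
        g = rng.binomial(2, 0.5, 40).astype(np.int8)
        rng.shuffle(g)
        est = site_fst(g[:20], g[20:])
        if est.fst is not None:
            vals.append(est.fst)
    assert abs(np.mean(vals)) < 0.02


def test_components_match_formula_oracle():
    """n1=6, n2=8, p1=0.75, p2=0.25, with explicit het counts."""
    g1 = _geno((1, 1, 4))   # p1 = 9/12 = 0.75, h1 = 1/6
    g2 = _geno((4, 4, 0))   # p2 = 4/16 = 0.25, h2 = 0.5
    r = site_fst(g1, g2)
    a, b, c = wc_oracle(6, 8, 0.75, 0.25, 1 / 6, 0.5)
    assert r.a == pytest.approx(a, rel=1e-12)
    assert r.b == pytest.approx(b, rel=1e-12)
    assert r.c == pytest.approx(c, rel=1e-12)
    assert r.fst == pytest.approx(a / (a + b + c), rel=1e-12)


def test_random_sites_match_oracle_and_vector_path():
    rng = np.random.default_rng(42)
    m = simulate_balding_nichols(rng.uniform(0.1, 0.9, 100), 0.2, (6, 8),
                                 rng=rng, missing_rate=0.05)
    design, _ = two_group_design(6, 8)
    design = GroupDesign({s: ("A" if s.startswith("g0") else "B")
                          for s in m.samples})
    table = fst_scan(m, design, "A", "B")
    for i in range(m.n_sites):
        g1, g2 = m.genotypes[i, :6], m.genotypes[i, 6:]
        c1, c2 = g1[g1 >= 0], g2[g2 >= 0]
        if len(c1) < 2 or len(c2) < 2:
            assert not table["usable"].iloc[i]
            continue
        a, b, c = wc_oracle(len(c1), len(c2), c1.mean() / 2, c2.mean() / 2,
                            (c1 == 1).mean(), (c2 == 1).mean())
        if a + b + c == 0:
            assert not table["usable"].iloc[i]
        else:
            assert table["fst"].iloc[i] == pytest.approx(a / (a + b + c),
                                                         rel=1e-9)


def test_small_group_skipped():
    r = site_fst(np.array([1, -1, -1, -1]), _geno((3, 3, 3)))
    assert r.skipped is not None and r.fst is None


def test_monomorphic_skipped():
    r = site_fst(_geno((5, 0, 0)), _geno((5, 0, 0)))
    assert r.skipped is not None


# ---------------------------------------------------------------------------
# windowed scan
# ---------------------------------------------------------------------------

def _matrix_from_sites(rows, n_a, n_b):
    """rows: (chrom, pos, genotypes_a, genotypes_b)"""
    sites = pd.DataFrame([(c, p, "A", "T") for c, p, *_ in rows],
                         columns=["chrom", "pos", "ref", "alt"])
    geno = np.array([list(ga) + list(gb) for _, _, ga, gb in rows],
                    dtype=np.int8)
    design, cols = two_group_design(n_a, n_b)
    return SnpMatrix(sites, geno, cols), design


def test_fixed_difference_window_significant(toy_layout):
    m, design = _matrix_from_sites(
        [("chr1", 5_000, [2] * 5, [0] * 5)], 5, 5)
    table = fst_scan(m, design, "A", "B")
    win = windowed_fst_pi(table, toy_layout, 100_000)
    first = win.iloc[0]
    assert first["mean_fst"] == pytest.approx(1.0)
    assert first["weighted_fst"] == pytest.approx(1.0)
    assert first["band"] == "significant"


def test_empty_window_excluded_from_banding(toy_layout):
    m, design = _matrix_from_sites(
        [("chr1", 5_000, [0] * 5, [0] * 5)], 5, 5)  # monomorphic
    table = fst_scan(m, design, "A", "B")
    win = windowed_fst_pi(table, toy_layout, 100_000)
    first = win.iloc[0]
    assert first["band"] is None
    assert first["pi_a"] == 0.0


def test_window_means_match_brute_force(toy_layout):
    rng = np.random.default_rng(9)
    m = simulate_balding_nichols(rng.uniform(0.1, 0.9, 500), 0.15, (10, 10),
                                 rng=rng)
    # scatter over chr1
    m.sites["pos"] = np.sort(rng.integers(0, 2_000_000, 500))
    design = GroupDesign({s: ("A" if s.startswith("g0") else "B")
                          for s in m.samples})
    table = fst_scan(m, design, "A", "B")
    win = windowed_fst_pi(table, toy_layout, 100_000)
    use = table[table["usable"]]
    for row in win[win["n_usable"] > 0].itertuples():
        sub = use[(use["chrom"] == row.chrom)
                  & (use["pos"] >= row.start) & (use["pos"] < row.end)]
        assert row.mean_fst == pytest.approx(sub["fst"].mean(), rel=1e-9)
        assert row.weighted_fst == pytest.approx(
            sub["a"].sum() / (sub["a"] + sub["b_c"]).sum(), rel=1e-9)


@pytest.mark.parametrize("fst,band", [
    (0.01, "minimal"), (0.05, "moderate"), (0.149, "moderate"),
    (0.15, "significant"), (0.8, "significant")])
def test_band_rule(fst, band):
    assert band_of(fst) == band


def test_pi_invariant_to_allele_swap(toy_layout):
    m, design = _matrix_from_sites(
        [("chr1", 1_000, [0, 1, 2, 1, 0], [1, 1, 0, 2, 2]),
         ("chr1", 2_000, [2, 1, 0, 1, 2], [1, 1, 2, 0, 0])], 5, 5)
    table = fst_scan(m, design, "A", "B")
    swapped = SnpMatrix(m.sites.copy(), (2 - m.genotypes).astype(np.int8),
                        m.samples)
    table2 = fst_scan(swapped, design, "A", "B")
    w1 = windowed_fst_pi(table, toy_layout, 100_000)
    w2 = windowed_fst_pi(table2, toy_layout, 100_000)
    assert w1["pi_a"].iloc[0] == pytest.approx(w2["pi_a"].iloc[0])
    assert w1["pi_b"].iloc[0] == pytest.approx(w2["pi_b"].iloc[0])


def test_svs_share_the_snp_estimator_path():
    """Identical genotype input gives identical estimates whether the
    markers arrive as SNPs or as SVs."""
    rng = np.random.default_rng(5)
    geno = rng.integers(0, 3, size=(30, 12)).astype(np.int8)
    design, cols = two_group_design(6, 6)
    sites = pd.DataFrame({"chrom": "chr1",
                          "pos": np.arange(30) * 1_000 + 100,
                          "ref": "A", "alt": "T"})
    snps = SnpMatrix(sites, geno, cols)
    svs = [SvRecord(f"sv{i}", "DEL", "chr1", int(1_000 * i + 100),
                    int(1_000 * i + 400), 300, tuple(int(g) for g in geno[i]))
           for i in range(30)]
    sv_m = svs_as_matrix(svs, cols)
    t1 = fst_scan(snps, design, "A", "B")
    t2 = fst_scan(sv_m, design, "A", "B")
    assert np.allclose(t1["fst"].to_numpy(), t2["fst"].to_numpy(),
                       equal_nan=True)


# ---------------------------------------------------------------------------
# gene profiles and marker comparison
# ---------------------------------------------------------------------------

def test_gene_flank_profile_subset_oracle(toy_layout):
    rng = np.random.default_rng(11)
    m = simulate_balding_nichols(rng.uniform(0.1, 0.9, 300), 0.2, (8, 8),
                                 rng=rng)
    m.sites["pos"] = np.sort(rng.integers(0, 200_000, 300))
    design = GroupDesign({s: ("A" if s.startswith("g0") else "B")
                          for s in m.samples})
    table = fst_scan(m, design, "A", "B")
    gene = GeneModel("g", "chr1", "+", 50_000, 80_000, ((50_000, 80_000),))
    prof = gene_flank_fst(table, gene, flank_bp=2_000)
    sub = table[(table["pos"] >= 48_000) & (table["pos"] < 82_000)
                & table["usable"]]
    assert prof["n_sites"] == len(sub)
    assert prof["mean_fst"] == pytest.approx(sub["fst"].mean(), rel=1e-9)


def test_gene_flank_empty_span_warns(toy_layout):
    table = pd.DataFrame({"chrom": ["chr1"], "pos": [900_000], "n1": [5],
                          "n2": [5], "p1": [0.5], "p2": [0.5], "a": [0.1],
                          "b_c": [0.2], "fst": [0.33], "usable": [True]})
    gene = GeneModel("g", "chr1", "+", 10_000, 12_000, ((10_000, 12_000),))
    with pytest.warns(UserWarning, match="no usable sites"):
        prof = gene_flank_fst(table, gene)
    assert np.isnan(prof["mean_fst"])


def _win(chrom, start, band):
    return {"chrom": chrom, "start": start, "end": start + 100_000,
            "band": band}


def test_marker_comparison_venn_counts():
    """3 shared + 2 SNP-only + 4 SV-only significant windows."""
    shared = [_win("chr1", i * 100_000, "significant") for i in range(3)]
    snp_only = [_win("chr1", (i + 10) * 100_000, "significant") for i in range(2)]
    sv_only = [_win("chr2", i * 100_000, "significant") for i in range(4)]
    filler = [_win("chr2", 800_000, "minimal"), _win("chr1", 1_900_000, "minimal")]
    snp_w = pd.DataFrame(shared + snp_only + filler)
    sv_w = pd.DataFrame(shared + sv_only + filler)
    genes = [GeneModel(f"g{i}", "chr1", "+", i * 100_000 + 10,
                       i * 100_000 + 5_000, ((i * 100_000 + 10, i * 100_000 + 5_000),))
             for i in range(13)]
    cmp_ = compare_marker_classes(snp_w, sv_w, genes)
    assert (cmp_.windows_shared, cmp_.windows_only_a, cmp_.windows_only_b) == (3, 2, 4)
    # genes under shared windows fall in the intersection
    assert cmp_.genes_shared == {"g0", "g1", "g2"}


def test_marker_comparison_identical_sets():
    w = pd.DataFrame([_win("chr1", 0, "significant"),
                      _win("chr1", 100_000, "minimal")])
    genes = [GeneModel("g", "chr1", "+", 10, 500, ((10, 500),))]
    cmp_ = compare_marker_classes(w, w, genes)
    assert cmp_.windows_only_a == cmp_.windows_only_b == 0
    assert cmp_.genes_shared == cmp_.genes_a == cmp_.genes_b


def test_marker_comparison_layout_mismatch():
    a = pd.DataFrame([_win("chr1", 0, "significant")])
    b = pd.DataFrame([_win("chr9", 0, "significant")])
    with pytest.raises(ValueError, match="layout"):
        compare_marker_classes(a, b, [])
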
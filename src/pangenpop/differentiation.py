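"""Weir-Cockerham FST and nucleotide diversity between two groups.

Per-site variance components follow the Weir & Cockerham (1984)
estimator for r = 2 populations of diploids; windowed summaries report
both the arithmetic mean of per-site estimates ("average FST") and the
ratio-of-sums ("weighted") estimate.  SNPs and SVs-as-biallelic-markers
run through the identical code path.

Differentiation bands on windowed mean FST: < 0.05 minimal,
0.05 <= FST < 0.15 moderate, >= 0.15 significant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_filters import MISSING, GeneModel, GenomeLayout, GroupDesign, SnpMatrix, SvRecord

BAND_EDGES = (0.05, 0.15)
BAND_NAMES = ("minimal", "moderate", "significant")


@dataclass
class SiteFst:
    a: float            # between-population variance component
    b: float            # between-individual within-population
    c: float            # within-individual (heterozygosity) component
    fst: float | None   # a / (a+b+c); None when undefined
    p: tuple[float, float]
    n: tuple[int, int]
    skipped: str | None = None


def _components(n1, n2, p1, p2, h1, h2):
    """Weir-Cockerham (1984) a, b, c for two populations of diploids.

    n_i: diploid sample sizes; p_i: alt-allele frequencies; h_i:
    observed heterozygote frequencies.  All arguments may be arrays.
    """
    r = 2.0
    n_bar = (n1 + n2) / r
    nc = (r * n_bar - (n1 ** 2 + n2 ** 2) / (r * n_bar)) / (r - 1)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
    a = (n_bar / nc) * (s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4)
                        / (n_bar - 1))
    b = (n_bar / (n_bar - 1)) * (p_bar * (1 - p_bar) - (r - 1) / r * s2
                                 - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
    c = h_bar / 2
    return a, b, c


def site_fst(genotypes_a, genotypes_b) -> SiteFst:
    """Weir-Cockerham estimate at one site from two groups' dosages.

    Dosages are 0/1/2 with -1 for missing.  Sites with fewer than two
    called genotypes in either group, or monomorphic across both groups
    (a + b + c = 0), are returned with ``skipped`` set.
    """
    g1 = np.asarray(genotypes_a)
    g2 = np.asarray(genotypes_b)
    c1, c2 = g1[g1 != MISSING], g2[g2 != MISSING]
    if len(c1) < 2 or len(c2) < 2:
        return SiteFst(np.nan, np.nan, np.nan, None,
                       (np.nan, np.nan), (len(c1), len(c2)),
                       skipped="fewer than 2 non-missing calls in a group")
    n1, n2 = len(c1), len(c2)
    p1, p2 = c1.mean() / 2, c2.mean() / 2
    h1, h2 = (c1 == 1).mean(), (c2 == 1).mean()
    a, b, c = _components(n1, n2, p1, p2, h1, h2)
    denom = a + b + c
    if denom == 0:
        return SiteFst(a, b, c, None, (p1, p2), (n1, n2),
                       skipped="monomorphic across both groups")
    return SiteFst(float(a), float(b), float(c), float(a / denom),
                   (float(p1), float(p2)), (n1, n2))


def _site_table(geno: np.ndarray, sites: pd.DataFrame,
                idx_a: list[int], idx_b: list[int]) -> pd.DataFrame:
    """Vectorised per-site components for all sites at once."""
    out = sites[["chrom", "pos"]].copy()
    ga, gb = geno[:, idx_a], geno[:, idx_b]
    called_a, called_b = ga != MISSING, gb != MISSING
    n1 = called_a.sum(axis=1).astype(float)
    n2 = called_b.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(called_a, ga, 0).sum(axis=1) / (2 * np.maximum(n1, 1))
        p2 = np.where(called_b, gb, 0).sum(axis=1) / (2 * np.maximum(n2, 1))
        h1 = (ga == 1).sum(axis=1) / np.maximum(n1, 1)
        h2 = (gb == 1).sum(axis=1) / np.maximum(n2, 1)
    usable = (n1 >= 2) & (n2 >= 2)
    a = np.full(len(out), np.nan)
    b = np.full(len(out), np.nan)
    c = np.full(len(out), np.nan)
    a[usable], b[usable], c[usable] = _components(
        n1[usable], n2[usable], p1[usable], p2[usable], h1[usable], h2[usable])
    denom = a + b + c
    fst = np.where(np.abs(denom) > 0, a / np.where(denom == 0, np.nan, denom),
                   np.nan)
    out["n1"], out["n2"] = n1, n2
    out["p1"], out["p2"] = p1, p2
    out["a"], out["b_c"] = a, b + c
    out["fst"] = fst
    out["usable"] = usable & ~np.isnan(fst)
    return out


def fst_scan(snps: SnpMatrix, design: GroupDesign,
             group_a: str, group_b: str) -> pd.DataFrame:
    """Per-site Weir-Cockerham components for a two-group contrast.

    Returns one row per site (chrom, pos, group sizes and frequencies,
    variance components, fst estimate, usable flag).  Per-site estimates
    are not clamped — negative values are expected under no
    differentiation and are retained in window means.
    """
    sa, sb = design.contrast(group_a, group_b)
    missing = [s for s in sa + sb if s not in snps.samples]
    if missing:
        raise ValueError(f"design samples absent from genotype matrix: {missing}")
    idx_a = [snps.samples.index(s) for s in sa]
    idx_b = [snps.samples.index(s) for s in sb]
    return _site_table(snps.genotypes, snps.sites, idx_a, idx_b)


def svs_as_matrix(svs: list[SvRecord], samples: list[str]) -> SnpMatrix:
    """View SV genotypes as a biallelic marker matrix keyed by start position.

    Runs SVs through the identical FST estimator path as SNPs.
    """
    sites = pd.DataFrame({
        "chrom": [s.chrom for s in svs],
        "pos": [s.start for s in svs],
        "ref": ["N"] * len(svs),
        "alt": ["<SV>"] * len(svs),
    })
    geno = (np.array([s.genotypes for s in svs], dtype=np.int8)
            if svs else np.empty((0, len(samples)), dtype=np.int8))
    order = np.lexsort((sites["pos"].to_numpy(),
                        sites["chrom"].to_numpy(dtype=object)))
    return SnpMatrix(sites.iloc[order].reset_index(drop=True), geno[order],
                     list(samples))


def band_of(mean_fst: float) -> str:
    if mean_fst < BAND_EDGES[0]:
        return BAND_NAMES[0]
    if mean_fst < BAND_EDGES[1]:
        return BAND_NAMES[1]
    return BAND_NAMES[2]


def windowed_fst_pi(site_table: pd.DataFrame, layout: GenomeLayout,
                    window_bp: int = 100_000) -> pd.DataFrame:
    """Windowed FST and per-group nucleotide diversity.

    Non-overlapping windows tile each chromosome from 0.  mean_fst is
    the arithmetic mean of usable per-site estimates; weighted_fst is
    sum(a) / sum(a + b + c) over the same sites.  Pi per group is
    sum over sites of 2 p (1-p) * 2n/(2n-1), divided by the window
    length in bp.  Windows with no usable (polymorphic) site keep
    Pi but get band None.
    """
    rows = []
    for chrom in layout.chromosomes:
        clen = layout.length_of(chrom)
        sub = site_table[site_table["chrom"] == chrom]
        widx = sub["pos"].to_numpy() // window_bp
        n_windows = math.ceil(clen / window_bp)
        for w in range(n_windows):
            start, end = w * window_bp, min((w + 1) * window_bp, clen)
            win = sub[widx == w]
            use = win[win["usable"]]
            span = end - start
            pi1 = _pi(win["p1"].to_numpy(), win["n1"].to_numpy()) / span
            pi2 = _pi(win["p2"].to_numpy(), win["n2"].to_numpy()) / span
            if len(use):
                mean_fst = float(use["fst"].mean())
                denom = float((use["a"] + use["b_c"]).sum())
                weighted = float(use["a"].sum() / denom) if denom else np.nan
                band = band_of(mean_fst)
            else:
                mean_fst = weighted = np.nan
                band = None
            rows.append((chrom, start, end, len(win), int(len(use)),
                         mean_fst, weighted, pi1, pi2, band))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites",
                                       "n_usable", "mean_fst", "weighted_fst",
                                       "pi_a", "pi_b", "band"])


def _pi(p: np.ndarray, n: np.ndarray) -> float:
    """Sum of unbiased per-site heterozygosity 2p(1-p) * 2n/(2n-1)."""
    good = n >= 1
    p, n = p[good], n[good]
    with np.errstate(invalid="ignore", divide="ignore"):
        contrib = 2 * p * (1 - p) * (2 * n / np.maximum(2 * n - 1, 1))
    return float(np.nansum(contrib))


def genome_weighted_fst(site_table: pd.DataFrame) -> float:
    """Genome-wide ratio-of-sums Weir-Cockerham estimate."""
    use = site_table[site_table["usable"]]
    denom = float((use["a"] + use["b_c"]).sum())
    if denom == 0:
        return float("nan")
    return float(use["a"].sum() / denom)


def gene_flank_fst(site_table: pd.DataFrame, gene: GeneModel,
                   flank_bp: int = 2_000) -> dict:
    """FST profile over a gene's span extended by +-flank_bp.

    Returns mean and weighted FST over the usable sites in the span plus
    the positional per-site series for plotting.  An empty span yields
    NaN summaries with a warning flag.
    """
    import warnings

    span = (gene.start - flank_bp, gene.end + flank_bp)
    sub = site_table[(site_table["chrom"] == gene.chrom)
                     & (site_table["pos"] >= span[0])
                     & (site_table["pos"] < span[1])]
    use = sub[sub["usable"]]
    if len(use) == 0:
        warnings.warn(f"no usable sites in {gene.gene_id} +-{flank_bp} bp")
        return {"gene": gene.gene_id, "n_sites": 0, "mean_fst": float("nan"),
                "weighted_fst": float("nan"),
                "series": sub[["pos", "fst"]].reset_index(drop=True)}
    denom = float((use["a"] + use["b_c"]).sum())
    return {
        "gene": gene.gene_id,
        "n_sites": int(len(use)),
        "mean_fst": float(use["fst"].mean()),
        "weighted_fst": float(use["a"].sum() / denom) if denom else float("nan"),
        "series": sub[["pos", "fst"]].reset_index(drop=True),
    }


@dataclass
class MarkerComparison:
    n_significant_a: int
    n_significant_b: int
    windows_shared: int
    windows_only_a: int
    windows_only_b: int
    genes_a: set
    genes_b: set
    genes_shared: set


def compare_marker_classes(windows_a: pd.DataFrame, windows_b: pd.DataFrame,
                           genes: list[GeneModel]) -> MarkerComparison:
    """Compare significantly differentiated windows from two marker classes.

    Both window tables must come from the same layout and banding.
    Windows in the 'significant' band are intersected as intervals;
    genes are attached to significant windows by span overlap.
    """
    for col in ("chrom", "start", "end", "band"):
        if col not in windows_a.columns or col not in windows_b.columns:
            raise ValueError("window tables must carry chrom/start/end/band")
    sig_a = windows_a[windows_a["band"] == "significant"]
    sig_b = windows_b[windows_b["band"] == "significant"]
    if not _same_layout(windows_a, windows_b):
        raise ValueError("window tables built on different layouts")

    shared = sum(_overlaps_any(r, sig_b) for r in sig_a.itertuples())
    only_a = len(sig_a) - shared
    only_b = len(sig_b) - sum(_overlaps_any(r, sig_a) for r in sig_b.itertuples())

    ga = _genes_in_windows(sig_a, genes)
    gb = _genes_in_windows(sig_b, genes)
    return MarkerComparison(len(sig_a), len(sig_b), shared, only_a, only_b,
                            ga, gb, ga & gb)


def _same_layout(wa: pd.DataFrame, wb: pd.DataFrame) -> bool:
    ca = wa.groupby("chrom")["end"].max()
    cb = wb.groupby("chrom")["end"].max()
    return ca.sort_index().equals(cb.sort_index())


def _overlaps_any(row, others: pd.DataFrame) -> bool:
    sub = others[others["chrom"] == row.chrom]
    return bool(((sub["start"] < row.end) & (row.start < sub["end"])).any())


def _genes_in_windows(windows: pd.DataFrame, genes: list[GeneModel]) -> set:
    out = set()
    for g in genes:
        sub = windows[windows["chrom"] == g.chrom]
        if ((sub["start"] < g.end) & (g.start < sub["end"])).any():
            out.add(g.gene_id)
    return out
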
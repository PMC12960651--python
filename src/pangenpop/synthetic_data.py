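"""Seeded generator of a complete synthetic pan-genome population study.

Emulates the statistical shape of a 27-accession resequencing panel:
a multi-chromosome layout with annotated genes, per-gene exon-coverage
fractions encoding a planted presence/absence structure (core,
U-shaped dispensable, private and subgroup-marker genes), trait-group
designs with planted differentially-present genes, Balding-Nichols
differentiated SNP genotypes, a per-SNP sweep-score track with planted
peaks, and a deletion-dominated SV set with planted breakpoint
hotspots.  Every output is a plain-text file that parses through
``pangenpop.io_filters``; ground truth is returned (and written as a
JSON/TSV sidecar) so each pipeline stage has a recovery test.

Outputs are byte-identical for identical seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_filters import (GeneModel, GenomeLayout, GroupDesign, SnpMatrix,
                         write_design, write_gene_models_gff3,
                         write_score_track)


@dataclass
class SimConfig:
    """Study-scale parameters; defaults are desk-scale but keep the
    panel structure of the emulated study (27 accessions in 3/3/21
    subgroups on 11 chromosomes)."""

    seed: int
    n_samples: int = 27
    subgroup_sizes: tuple[int, ...] = (3, 3, 21)
    n_chromosomes: int = 11
    chrom_length_bp: int = 2_000_000

    # genes
    n_genes: int = 2_000
    gene_length_range: tuple[int, int] = (2_000, 6_000)
    max_exons: int = 5
    core_fraction: float = 0.761       # mirrors the observed pan-genome mix
    dispensable_fraction: float = 0.231
    private_fraction: float = 0.008
    dispensable_freq_beta: tuple[float, float] = (0.3, 0.3)  # U-shaped
    n_subgroup_marker_genes: int = 100  # per minor subgroup, from the dispensable pool
    marker_p_in: float = 0.95
    marker_p_out: float = 0.05
    n_differential_genes: int = 30
    differential_p: tuple[float, float] = (0.95, 0.05)

    # coverage model (covered exon-base fraction at depth >= min_cov)
    present_coverage_beta: tuple[float, float] = (15.0, 1.0)
    absent_residual_max: float = 0.1   # absent genes ~ U(0, this); 0 = noise-free

    # SNPs and sweep score track
    n_snps: int = 20_000
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9)
    fst: float = 0.15
    snp_missing_rate: float = 0.01
    n_sweep_peaks: int = 8
    sweep_peak_width_bp: int = 137_500
    sweep_peak_elevation: float = 10.0

    # SVs (deletion-dominated mix)
    n_dels: int = 1_550
    n_dups: int = 445
    n_ins: int = 5
    sv_length_log_mean: float = 6.5
    sv_length_log_sd: float = 1.0
    sv_min_length: int = 60
    sv_freq_range: tuple[float, float] = (0.05, 0.9)
    sv_missing_rate: float = 0.01
    n_hotspot_clusters: int = 10
    hotspot_width_bp: int = 100_000
    hotspot_spacing_bp: int = 200_000  # lattice pitch for cluster placement
    hotspot_breakpoint_share: float = 0.85

    def validate(self) -> None:
        fr = self.core_fraction + self.dispensable_fraction + self.private_fraction
        if abs(fr - 1.0) > 1e-9:
            raise ValueError("gene category fractions must sum to 1")
        if sum(self.subgroup_sizes) != self.n_samples:
            raise ValueError("subgroup sizes must sum to n_samples")
        if not 0 < self.fst < 1:
            raise ValueError("fst must lie strictly between 0 and 1")
        if self.absent_residual_max >= 0.2:
            raise ValueError("absent residual coverage must stay below the "
                             "presence cutoff")
        n_disp = round(self.n_genes * self.dispensable_fraction)
        reserved = 2 * self.n_subgroup_marker_genes + self.n_differential_genes
        if reserved > n_disp:
            raise ValueError("marker + differential genes exceed the "
                             "dispensable pool")
        if round(self.n_genes * self.private_fraction) > 0 and self.n_samples < 1:
            raise ValueError("private genes require at least one sample")


@dataclass
class SyntheticTruth:
    presence: pd.DataFrame                 # genes x samples, planted truth
    categories: pd.Series                  # planted category per gene
    differential_genes: list[str]
    subgroup_labels: dict[str, int]
    sweep_intervals: list[tuple[str, int, int]]
    hotspot_intervals: list[tuple[str, int, int]]
    fst: float


@dataclass
class StudyBundle:
    layout: GenomeLayout
    genes_gff3: Path
    coverage_tsv: Path
    snp_vcf: Path
    score_tsv: Path
    sv_vcf: Path
    design_tsv: Path
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# Balding-Nichols genotypes
# ---------------------------------------------------------------------------

def simulate_balding_nichols(p_ancestral, F: float, group_sizes,
                             n_loci: int | None = None,
                             seed: int | None = None,
                             rng: np.random.Generator | None = None,
                             missing_rate: float = 0.0) -> SnpMatrix:
    """Diploid genotypes for populations diverged under drift parameter F.

    Each population's allele frequency at a locus is drawn from
    Beta(p(1-F)/F, (1-p)(1-F)/F) around the ancestral frequency p, so
    the expected fixation index between populations is approximately F.
    Genotypes are Binomial(2, population frequency).  Samples are named
    g<group>_s<index>.
    """
    if not 0 < F < 1:
        raise ValueError("F must lie strictly between 0 and 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    p = np.asarray(p_ancestral, dtype=float)
    if p.ndim == 0:
        if n_loci is None:
            raise ValueError("scalar ancestral frequency needs n_loci")
        p = np.full(n_loci, float(p))
    n_loci = len(p)
    a, b = p * (1 - F) / F, (1 - p) * (1 - F) / F
    cols, names = [], []
    for gi, size in enumerate(group_sizes):
        q = rng.beta(a, b)
        cols.append(rng.binomial(2, q[:, None], size=(n_loci, size)))
        names.extend(f"g{gi}_s{j}" for j in range(size))
    geno = np.concatenate(cols, axis=1).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random(geno.shape) < missing_rate
        geno[mask] = -1
    sites = pd.DataFrame({"chrom": "chr1", "pos": np.arange(n_loci),
                          "ref": "A", "alt": "T"})
    return SnpMatrix(sites, geno, names)


# ---------------------------------------------------------------------------
# Full study simulation
# ---------------------------------------------------------------------------

def _make_layout(cfg: SimConfig) -> GenomeLayout:
    return GenomeLayout(tuple(f"chr{i + 1}" for i in range(cfg.n_chromosomes)),
                        tuple([cfg.chrom_length_bp] * cfg.n_chromosomes))


def _make_genes(cfg: SimConfig, layout: GenomeLayout,
                rng: np.random.Generator) -> list[GeneModel]:
    genes = []
    per_chrom = np.array_split(np.arange(cfg.n_genes), cfg.n_chromosomes)
    lo, hi = cfg.gene_length_range
    for ci, ids in enumerate(per_chrom):
        chrom = layout.chromosomes[ci]
        clen = layout.lengths[ci]
        usable = clen - len(ids) * hi - 1000
        mean_gap = max(usable / max(len(ids), 1), 200)
        cursor = 500
        for gid in ids:
            length = int(rng.integers(lo, hi + 1))
            gap = int(rng.exponential(mean_gap * 0.5)) + 100
            start = cursor + gap
            end = start + length
            if end >= clen - 500:   # wrap guard; keeps genes on-chromosome
                start = int(rng.integers(500, clen - hi - 500))
                end = start + length
            cursor = max(cursor, end)
            n_ex = int(rng.integers(1, cfg.max_exons + 1))
            bounds = np.sort(rng.choice(np.arange(1, length), size=2 * n_ex - 2,
                                        replace=False)) if n_ex > 1 else np.array([], int)
            pts = np.concatenate([[0], bounds, [length]])
            exons = tuple((start + int(pts[2 * k]), start + int(pts[2 * k + 1]))
                          for k in range(n_ex))
            exons = tuple((s, e) for s, e in exons if e > s) or ((start, end),)
            genes.append(GeneModel(f"gene{gid:05d}", chrom, "+" if rng.random() < 0.5
                                   else "-", start, end, exons))
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def _plant_presence(cfg: SimConfig, samples: list[str], subgroup: np.ndarray,
                    contrast: np.ndarray, rng: np.random.Generator):
    """Build the planted presence matrix and category/differential truth."""
    n, G = cfg.n_samples, cfg.n_genes
    n_core = round(G * cfg.core_fraction)
    n_priv = round(G * cfg.private_fraction)
    n_disp = G - n_core - n_priv
    gene_ids = [f"gene{i:05d}" for i in range(G)]
    order = rng.permutation(G)
    core_idx = order[:n_core]
    disp_idx = order[n_core:n_core + n_disp]
    priv_idx = order[n_core + n_disp:]

    presence = np.zeros((G, n), dtype=np.int8)
    presence[core_idx] = 1
    for i in priv_idx:
        presence[i, rng.integers(0, n)] = 1

    # dispensable pool: subgroup markers, differential genes, then U-shaped rest
    disp = list(disp_idx)
    markers1 = disp[:cfg.n_subgroup_marker_genes]
    markers2 = disp[cfg.n_subgroup_marker_genes:2 * cfg.n_subgroup_marker_genes]
    k = 2 * cfg.n_subgroup_marker_genes
    differential = disp[k:k + cfg.n_differential_genes]
    rest = disp[k + cfg.n_differential_genes:]

    for sg, markers in ((0, markers1), (1, markers2)):
        in_g = subgroup == sg
        for i in markers:
            p = np.where(in_g, cfg.marker_p_in, cfg.marker_p_out)
            presence[i] = rng.random(n) < p
    pa, pb = cfg.differential_p
    in_a = contrast == 0
    for i in differential:
        p = np.where(in_a, pa, pb)
        presence[i] = rng.random(n) < p
    alpha, beta = cfg.dispensable_freq_beta
    for i in rest:
        f = rng.beta(alpha, beta)
        row = rng.random(n) < f
        if row.sum() == 0:          # keep dispensable genes present somewhere
            row[rng.integers(0, n)] = True
        presence[i] = row

    cats = np.empty(G, dtype=object)
    cats[core_idx] = "core"
    cats[disp_idx] = "dispensable"
    cats[priv_idx] = "private"
    pres_df = pd.DataFrame(presence, index=gene_ids, columns=samples)
    return (pres_df, pd.Series(cats, index=gene_ids, name="category"),
            [gene_ids[i] for i in differential])


def _coverage_from_presence(cfg: SimConfig, presence: pd.DataFrame,
                            rng: np.random.Generator) -> pd.DataFrame:
    a, b = cfg.present_coverage_beta
    mat = presence.to_numpy(dtype=bool)
    frac = np.where(mat, rng.beta(a, b, size=mat.shape),
                    rng.uniform(0, max(cfg.absent_residual_max, 1e-12),
                                size=mat.shape)
                    if cfg.absent_residual_max > 0 else 0.0)
    long = pd.DataFrame(frac, index=presence.index, columns=presence.columns) \
        .reset_index(names="gene") \
        .melt(id_vars="gene", var_name="sample", value_name="covered_fraction")
    return long.sort_values(["gene", "sample"], kind="mergesort").reset_index(drop=True)


def _write_snp_vcf(path, layout: GenomeLayout, sites: pd.DataFrame,
                   geno: np.ndarray, samples: list[str]) -> None:
    gt_map = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c, l in zip(layout.chromosomes, layout.lengths):
            fh.write(f"##contig=<ID={c},length={l}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for i, row in enumerate(sites.itertuples()):
            gts = "\t".join(gt_map[int(g)] for g in geno[i])
            fh.write(f"{row.chrom}\t{row.pos + 1}\tsnp{i}\t{row.ref}\t{row.alt}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")


def _write_sv_vcf(path, layout: GenomeLayout, svs: list[dict],
                  samples: list[str]) -> None:
    gt_map = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c, l in zip(layout.chromosomes, layout.lengths):
            fh.write(f"##contig=<ID={c},length={l}>\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##ALT=<ID=DEL,Description=\"Deletion\">\n")
        fh.write("##ALT=<ID=DUP,Description=\"Duplication\">\n")
        fh.write("##ALT=<ID=INS,Description=\"Insertion\">\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for sv in svs:
            svlen = -sv["length"] if sv["type"] == "DEL" else sv["length"]
            end = sv["end"] if sv["type"] != "INS" else sv["start"] + 1
            info = f"SVTYPE={sv['type']};END={end};SVLEN={svlen}"
            gts = "\t".join(gt_map[int(g)] for g in sv["geno"])
            fh.write(f"{sv['chrom']}\t{sv['start'] + 1}\t{sv['id']}\tN\t"
                     f"<{sv['type']}>\t.\tPASS\t{info}\tGT\t{gts}\n")


def simulate_study(cfg: SimConfig, outdir) -> StudyBundle:
    """Generate the full synthetic study bundle under ``outdir``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    layout = _make_layout(cfg)
    samples = [f"acc{i + 1:02d}" for i in range(cfg.n_samples)]
    subgroup = np.repeat(np.arange(len(cfg.subgroup_sizes)),
                         cfg.subgroup_sizes)
    # trait contrast: the two minor subgroups vs the main panel
    contrast = np.where(subgroup < 2, 0, 1)
    design = GroupDesign({s: ("cold_tolerant" if c == 0 else "cold_sensitive")
                          for s, c in zip(samples, contrast)})

    genes = _make_genes(cfg, layout, rng)
    presence, categories, differential = _plant_presence(
        cfg, samples, subgroup, contrast, rng)
    coverage = _coverage_from_presence(cfg, presence, rng)

    # SNPs: Balding-Nichols between the two contrast groups
    lo, hi = cfg.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, size=cfg.n_snps)
    sizes = (int((contrast == 0).sum()), int((contrast == 1).sum()))
    bn = simulate_balding_nichols(p_anc, cfg.fst, sizes, rng=rng,
                                  missing_rate=cfg.snp_missing_rate)
    chrom_idx = rng.integers(0, cfg.n_chromosomes, size=cfg.n_snps)
    pos = rng.integers(0, cfg.chrom_length_bp, size=cfg.n_snps)
    snp_sites = pd.DataFrame({
        "chrom": [layout.chromosomes[i] for i in chrom_idx],
        "pos": pos, "ref": "A", "alt": "T"})
    order = np.lexsort((snp_sites["pos"].to_numpy(),
                        snp_sites["chrom"].to_numpy(dtype=object)))
    snp_sites = snp_sites.iloc[order].reset_index(drop=True)
    snp_geno = bn.genotypes[order]

    # sweep-score track over SNP positions: Exponential(1) background,
    # planted peak intervals multiplied by the elevation factor
    scores = rng.exponential(1.0, size=cfg.n_snps)
    sweep_intervals = []
    peak_chroms = rng.choice(cfg.n_chromosomes, size=cfg.n_sweep_peaks,
                             replace=False) if cfg.n_sweep_peaks <= cfg.n_chromosomes \
        else rng.integers(0, cfg.n_chromosomes, size=cfg.n_sweep_peaks)
    for ci in peak_chroms:
        start = int(rng.integers(0, cfg.chrom_length_bp - cfg.sweep_peak_width_bp))
        end = start + cfg.sweep_peak_width_bp
        chrom = layout.chromosomes[ci]
        sweep_intervals.append((chrom, start, end))
        in_peak = ((snp_sites["chrom"] == chrom)
                   & (snp_sites["pos"] >= start) & (snp_sites["pos"] < end))
        scores[in_peak.to_numpy()] *= cfg.sweep_peak_elevation
    score_track = pd.DataFrame({"chrom": snp_sites["chrom"],
                                "pos": snp_sites["pos"],
                                "score": scores})

    # SVs with planted hotspot clusters
    svs, hotspot_intervals = _make_svs(cfg, layout, rng)

    # write everything
    genes_gff3 = outdir / "genes.gff3"
    write_gene_models_gff3(genes, genes_gff3)
    coverage_tsv = outdir / "coverage.tsv"
    coverage.to_csv(coverage_tsv, sep="\t", index=False)
    snp_vcf = outdir / "snps.vcf"
    _write_snp_vcf(snp_vcf, layout, snp_sites, snp_geno, samples)
    score_tsv = outdir / "xpclr_scores.tsv"
    write_score_track(score_track, score_tsv)
    sv_vcf = outdir / "svs.vcf"
    _write_sv_vcf(sv_vcf, layout, svs, samples)
    design_tsv = outdir / "design.tsv"
    write_design(design, design_tsv)

    truth = SyntheticTruth(presence, categories, differential,
                           dict(zip(samples, (int(x) for x in subgroup))),
                           sweep_intervals,
                           hotspot_intervals, cfg.fst)
    _write_truth(outdir, truth, layout)
    return StudyBundle(layout, genes_gff3, coverage_tsv, snp_vcf, score_tsv,
                       sv_vcf, design_tsv, truth)


def _make_svs(cfg: SimConfig, layout: GenomeLayout, rng: np.random.Generator):
    # planted clusters sit centred on distinct slots of a fixed lattice, so
    # each cluster is non-overlapping and projects onto a single dominant
    # scan window — the planted truth stays identifiable by a windowed scan
    slots = [(c, s) for c, l in zip(layout.chromosomes, layout.lengths)
             for s in range(l // cfg.hotspot_spacing_bp)]
    if cfg.n_hotspot_clusters > len(slots):
        raise ValueError("more hotspot clusters than placement slots")
    pick = rng.choice(len(slots), size=cfg.n_hotspot_clusters, replace=False)
    margin = (cfg.hotspot_spacing_bp - cfg.hotspot_width_bp) // 2
    hotspot_intervals = []
    for i in sorted(pick):
        chrom, slot = slots[i]
        start = slot * cfg.hotspot_spacing_bp + max(margin, 0)
        hotspot_intervals.append((chrom, start, start + cfg.hotspot_width_bp))
    total = cfg.n_dels + cfg.n_dups + cfg.n_ins
    types = (["DEL"] * cfg.n_dels + ["DUP"] * cfg.n_dups + ["INS"] * cfg.n_ins)
    rng.shuffle(types)
    svs = []
    lo_f, hi_f = cfg.sv_freq_range
    for i, t in enumerate(types):
        length = int(np.clip(rng.lognormal(cfg.sv_length_log_mean,
                                           cfg.sv_length_log_sd),
                             cfg.sv_min_length, 50_000))
        in_cluster = rng.random() < cfg.hotspot_breakpoint_share
        if in_cluster:
            chrom, cs, ce = hotspot_intervals[int(rng.integers(
                0, cfg.n_hotspot_clusters))]
            start = int(rng.integers(cs, max(ce - length, cs + 1)))
        else:
            chrom = layout.chromosomes[int(rng.integers(0, cfg.n_chromosomes))]
            start = int(rng.integers(0, cfg.chrom_length_bp - length - 1))
        end = start if t == "INS" else start + length
        f = rng.uniform(lo_f, hi_f)
        geno = rng.binomial(2, f, size=cfg.n_samples).astype(np.int8)
        if cfg.sv_missing_rate > 0:
            geno[rng.random(cfg.n_samples) < cfg.sv_missing_rate] = -1
        svs.append({"id": f"sv{i:05d}", "type": t, "chrom": chrom,
                    "start": start, "end": end, "length": length,
                    "geno": geno})
    svs.sort(key=lambda s: (s["chrom"], s["start"], s["id"]))
    return svs, hotspot_intervals


def _write_truth(outdir: Path, truth: SyntheticTruth, layout: GenomeLayout) -> None:
    truth.presence.to_csv(outdir / "truth_presence.tsv", sep="\t")
    truth.categories.to_csv(outdir / "truth_categories.tsv", sep="\t")
    meta = {
        "differential_genes": truth.differential_genes,
        "subgroup_labels": truth.subgroup_labels,
        "sweep_intervals": truth.sweep_intervals,
        "hotspot_intervals": truth.hotspot_intervals,
        "fst": truth.fst,
        "layout": {c: l for c, l in zip(layout.chromosomes, layout.lengths)},
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
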
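"""Readers, writers and variant-level filters shared by every pipeline stage.

All coordinates are handled internally as 0-based half-open intervals;
1-based formats (VCF, GFF3) are converted at the boundary.  Score-track
TSVs use the internal 0-based convention directly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1  # genotype sentinel: alt-allele dosage unknown

SV_TYPES = ("DEL", "DUP", "INS")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths (bp)."""

    chromosomes: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self):
        if len(self.chromosomes) != len(self.lengths):
            raise ValueError("chromosomes and lengths differ in number")
        if len(set(self.chromosomes)) != len(self.chromosomes):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("chromosome lengths must be positive")

    @classmethod
    def from_dict(cls, d: dict[str, int]) -> "GenomeLayout":
        return cls(tuple(d.keys()), tuple(int(v) for v in d.values()))

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths[self.chromosomes.index(chrom)]
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chromosomes


@dataclass(frozen=True)
class GeneModel:
    """A gene with its exon structure, 0-based half-open coordinates."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene without exons rejected")
        if self.end <= self.start:
            raise ValueError(f"{self.gene_id}: empty span")
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"{self.gene_id}: empty exon [{s},{e})")
            if s < self.start or e > self.end:
                raise ValueError(f"{self.gene_id}: exon outside gene span")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or unsorted")
            prev_end = e

    @property
    def exon_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class SnpMatrix:
    """Biallelic SNP sites with per-sample alt-allele dosages.

    ``sites`` holds chrom, pos (0-based), ref, alt; ``genotypes`` is an
    int8 array of shape (n_sites, n_samples) with values 0/1/2 and -1 for
    a missing call.
    """

    sites: pd.DataFrame
    genotypes: np.ndarray
    samples: list[str]

    def __post_init__(self):
        if self.genotypes.shape != (len(self.sites), len(self.samples)):
            raise ValueError("genotype array shape does not match sites/samples")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def subset_samples(self, names: list[str]) -> "SnpMatrix":
        idx = [self.samples.index(s) for s in names]
        return SnpMatrix(self.sites.reset_index(drop=True),
                         self.genotypes[:, idx], list(names))


@dataclass(frozen=True)
class SvRecord:
    """One structural variant with per-sample genotypes (dosage of the SV allele)."""

    sv_id: str
    type: str
    chrom: str
    start: int  # 0-based
    end: int    # half-open; == start for INS
    length: int
    genotypes: tuple[int, ...]

    def __post_init__(self):
        if self.type not in SV_TYPES:
            raise ValueError(f"{self.sv_id}: unsupported SV type {self.type}")
        if self.end < self.start:
            raise ValueError(f"{self.sv_id}: end < start")
        if self.type in ("DEL", "DUP") and self.length != self.end - self.start:
            raise ValueError(f"{self.sv_id}: DEL/DUP length must equal end-start")
        if self.type == "INS" and self.end != self.start:
            raise ValueError(f"{self.sv_id}: INS must have end == start")

    @property
    def interval(self) -> tuple[int, int]:
        """Genomic footprint; INS is the single-bp point of insertion."""
        if self.type == "INS":
            return (self.start, self.start + 1)
        return (self.start, self.end)

    @property
    def breakpoints(self) -> tuple[int, ...]:
        if self.type == "INS":
            return (self.start,)
        return (self.start, self.end)


@dataclass
class GroupDesign:
    """Sample-to-group assignment for a two-group contrast."""

    assignments: dict[str, str]

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.assignments.items() if g == group]

    @property
    def groups(self) -> list[str]:
        seen = []
        for g in self.assignments.values():
            if g not in seen:
                seen.append(g)
        return seen

    def contrast(self, group_a: str, group_b: str) -> tuple[list[str], list[str]]:
        a, b = self.samples_in(group_a), self.samples_in(group_b)
        if not a or not b:
            raise ValueError(f"empty contrast group: {group_a if not a else group_b}")
        return a, b


# ---------------------------------------------------------------------------
# Genotype helpers
# ---------------------------------------------------------------------------

def _dosage_from_cyvcf2(gt_types: np.ndarray) -> np.ndarray:
    """Map cyvcf2 gt_types (0=HOM_REF,1=HET,2=UNKNOWN,3=HOM_ALT) to dosage."""
    out = np.full(gt_types.shape, MISSING, dtype=np.int8)
    out[gt_types == 0] = 0
    out[gt_types == 1] = 1
    out[gt_types == 3] = 2
    return out


def missing_fraction(genotypes: np.ndarray) -> np.ndarray:
    """Per-site fraction of missing calls; genotypes (n_sites, n_samples)."""
    return (genotypes == MISSING).mean(axis=1)


def minor_allele_frequency(genotypes: np.ndarray) -> np.ndarray:
    """Per-site MAF computed from non-missing calls only.

    Sites with no called genotypes get MAF 0 (monomorphic by convention).
    """
    called = genotypes != MISSING
    n_called = called.sum(axis=1)
    alt = np.where(called, genotypes, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, alt / (2 * np.maximum(n_called, 1)), 0.0)
    return np.minimum(p, 1 - p)


# ---------------------------------------------------------------------------
# VCF readers
# ---------------------------------------------------------------------------

def read_snp_vcf(path, max_missing_keep_fraction: float = 0.7,
                 min_maf: float = 0.05) -> SnpMatrix:
    """Read a population SNP VCF, keeping high-quality biallelic sites.

    Parameters mirror the vcftools idiom: a site is kept when its
    fraction of called genotypes is at least ``max_missing_keep_fraction``
    (i.e. missingness <= 1 - that value) and its minor allele frequency,
    computed over non-missing calls, is at least ``min_maf``.

    Note on defaults: min_maf defaults to 0.05 ("MAF < 5% removed"); pass
    another value to change the screen.
    """
    from cyvcf2 import VCF

    for name, v in (("max_missing_keep_fraction", max_missing_keep_fraction),
                    ("min_maf", min_maf)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0,1]")

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, dosages = [], []
    n_not_biallelic = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or not rec.is_snp:
            n_not_biallelic += 1
            continue
        rows.append((rec.CHROM, rec.POS - 1, rec.REF, rec.ALT[0]))
        dosages.append(_dosage_from_cyvcf2(np.asarray(rec.gt_types)))
    vcf.close()
    if n_not_biallelic:
        logger.info("read_snp_vcf: dropped %d non-biallelic/non-SNP records",
                    n_not_biallelic)
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    geno = (np.asarray(dosages, dtype=np.int8)
            if dosages else np.empty((0, len(samples)), dtype=np.int8))

    keep = ((missing_fraction(geno) <= 1 - max_missing_keep_fraction)
            & (minor_allele_frequency(geno) >= min_maf))
    sites, geno = sites[keep].reset_index(drop=True), geno[keep]

    order = np.lexsort((sites["pos"].to_numpy(),
                        sites["chrom"].to_numpy(dtype=object)))
    return SnpMatrix(sites.iloc[order].reset_index(drop=True), geno[order], samples)


def read_sv_vcf(path, min_length: int = 50, max_missing_fraction: float = 0.5,
                min_maf: float = 0.01) -> tuple[list[SvRecord], list[str]]:
    """Read an SV VCF (DEL/DUP/INS) and apply the population filters.

    Keeps records with length strictly greater than ``min_length``,
    missing-call fraction <= ``max_missing_fraction`` and MAF >= ``min_maf``.
    Returns (records, samples).  Types outside DEL/DUP/INS and records
    lacking both END and SVLEN are dropped with a logged count.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records: list[SvRecord] = []
    n_bad_type = n_no_coords = 0
    for i, rec in enumerate(vcf):
        svtype = rec.INFO.get("SVTYPE")
        if svtype not in SV_TYPES:
            n_bad_type += 1
            continue
        end_field = rec.INFO.get("END")
        svlen = rec.INFO.get("SVLEN")
        if isinstance(svlen, (tuple, list)):
            svlen = svlen[0]
        start = rec.POS - 1
        if svtype == "INS":
            if svlen is None:
                n_no_coords += 1
                continue
            length, end = abs(int(svlen)), start
        else:
            if end_field is not None:
                end = int(end_field)        # VCF END is 1-based inclusive
            elif svlen is not None:
                end = start + abs(int(svlen))
            else:
                n_no_coords += 1
                continue
            length = end - start
        geno = _dosage_from_cyvcf2(np.asarray(rec.gt_types))
        if length <= min_length:
            continue
        if (geno == MISSING).mean() > max_missing_fraction:
            continue
        if minor_allele_frequency(geno[None, :])[0] < min_maf:
            continue
        sv_id = rec.ID or f"sv{i}"
        records.append(SvRecord(sv_id, svtype, rec.CHROM, start, end,
                                length, tuple(int(g) for g in geno)))
    vcf.close()
    if n_bad_type:
        logger.info("read_sv_vcf: dropped %d records with unsupported SVTYPE",
                    n_bad_type)
    if n_no_coords:
        logger.warning("read_sv_vcf: dropped %d records lacking END and SVLEN",
                       n_no_coords)
    records.sort(key=lambda r: (r.chrom, r.start, r.sv_id))
    return records, samples


# ---------------------------------------------------------------------------
# Gene models: GFF3 and BED12
# ---------------------------------------------------------------------------

def read_gene_models(path) -> list[GeneModel]:
    """Read gene models from GFF3 or BED12, sorted by (chrom, start)."""
    p = str(path)
    if p.endswith((".bed", ".bed12")):
        genes = _read_bed12(p)
    else:
        genes = _read_gff3(p)
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def _read_gff3(path: str) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(path, ":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique")
    genes = []
    for g in db.features_of_type("gene"):
        exons = sorted((e.start - 1, e.end)
                       for e in db.children(g, featuretype="exon"))
        if not exons:
            raise ValueError(f"gene {g.id} has zero exons")
        merged = _merge_intervals(exons)
        genes.append(GeneModel(g.id, g.seqid, g.strand if g.strand in "+-" else "+",
                               g.start - 1, g.end, tuple(merged)))
    return genes


def _read_bed12(path: str) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5] if len(f) > 5 else "+"
            if len(f) >= 12:
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
                exons = tuple((start + s, start + s + sz)
                              for s, sz in zip(starts, sizes))
            else:
                exons = ((start, end),)
            genes.append(GeneModel(name, chrom, strand, start, end, exons))
    return genes


def _merge_intervals(ivals):
    out = []
    for s, e in ivals:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def write_gene_models_gff3(genes: list[GeneModel], path) -> None:
    """Write gene models as minimal GFF3 (gene/mRNA/exon records)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            base = f"{g.chrom}\tpangenpop\t"
            tail = f"\t.\t{g.strand}\t."
            fh.write(f"{base}gene\t{g.start + 1}\t{g.end}{tail}\tID={g.gene_id}\n")
            mrna = f"{g.gene_id}.t1"
            fh.write(f"{base}mRNA\t{g.start + 1}\t{g.end}{tail}\t"
                     f"ID={mrna};Parent={g.gene_id}\n")
            for k, (s, e) in enumerate(g.exons, 1):
                fh.write(f"{base}exon\t{s + 1}\t{e}{tail}\t"
                         f"ID={mrna}.exon{k};Parent={mrna}\n")


def write_gene_models_bed12(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            starts = ",".join(str(s - g.start) for s, e in g.exons)
            fh.write("\t".join([g.chrom, str(g.start), str(g.end), g.gene_id,
                                "0", g.strand, str(g.start), str(g.end), "0",
                                str(len(g.exons)), sizes, starts]) + "\n")


# ---------------------------------------------------------------------------
# Score tracks, designs, region BED
# ---------------------------------------------------------------------------

def read_score_track(path) -> pd.DataFrame:
    """Read a per-site score TSV with columns chrom, pos, score.

    Positions are 0-based.  Unsorted input is sorted with a warning; an
    empty file yields an empty track with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    expected = ["chrom", "pos", "score"]
    if list(df.columns[:3]) != expected:
        raise ValueError(f"score track needs columns {expected}, got {list(df.columns)}")
    if df.empty:
        warnings.warn(f"empty score track: {path}")
        return df
    if not df.groupby("chrom", sort=False)["pos"].is_monotonic_increasing.all():
        warnings.warn("score track positions unsorted; sorting")
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def write_score_track(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_design(path) -> GroupDesign:
    """Read a sample-to-group TSV (columns: sample, group)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df["sample"].duplicated().any():
        dups = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"samples assigned to multiple groups: {dups}")
    return GroupDesign(dict(zip(df["sample"], df["group"])))


def write_design(design: GroupDesign, path) -> None:
    pd.DataFrame(design.assignments.items(), columns=["sample", "group"]).to_csv(
        path, sep="\t", index=False)


def write_regions_bed(regions, path) -> None:
    """Write (chrom, start, end[, name[, score]]) tuples as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write("\t".join(str(x) for x in r) + "\n")


def read_regions_bed(path) -> list[tuple]:
    out = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                continue
            out.append((f[0], int(f[1]), int(f[2]), *f[3:]))
    return out
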
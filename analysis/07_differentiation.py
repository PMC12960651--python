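#!/usr/bin/env python
"""Windowed FST / Pi scans for SNPs and SVs, and their comparison.

Weir-Cockerham per-site estimates between the trait groups, averaged in
100 kb windows with differentiation bands (0.05 / 0.15), run once on
SNPs and once on SVs-as-biallelic-markers, then compared window-wise
and gene-wise.
"""

import argparse
import json
from pathlib import Path

from _common import results_dir

from pangenpop import io_filters as io
from pangenpop.differentiation import (compare_marker_classes, fst_scan,
                                       genome_weighted_fst, svs_as_matrix,
                                       windowed_fst_pi)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--bundle", type=Path, default=Path("scratch/simdata"))
    ap.add_argument("--window", type=int, default=100_000)
    args = ap.parse_args()
    res = results_dir()

    design = io.read_design(args.bundle / "design.tsv")
    with open(args.bundle / "truth.json") as fh:
        layout = io.GenomeLayout.from_dict(json.load(fh)["layout"])
    groups = ("cold_tolerant", "cold_sensitive")

    snps = io.read_snp_vcf(args.bundle / "snps.vcf")
    snp_sites = fst_scan(snps, design, *groups)
    print(f"SNP genome-wide weighted FST: "
          f"{genome_weighted_fst(snp_sites):.4f} ({snps.n_sites} sites)")
    snp_win = windowed_fst_pi(snp_sites, layout, args.window)
    snp_win.to_csv(res / "fst_windows_snp.tsv", sep="\t", index=False)

    svs, samples = io.read_sv_vcf(args.bundle / "svs.vcf")
    sv_sites = fst_scan(svs_as_matrix(svs, samples), design, *groups)
    sv_win = windowed_fst_pi(sv_sites, layout, args.window)
    sv_win.to_csv(res / "fst_windows_sv.tsv", sep="\t", index=False)

    for name, win in (("SNP", snp_win), ("SV", sv_win)):
        bands = win["band"].value_counts(dropna=True).to_dict()
        print(f"{name} windows by band: {bands}")

    genes = io.read_gene_models(args.bundle / "genes.gff3")
    cmp_ = compare_marker_classes(snp_win, sv_win, genes)
    print(f"significant windows: SNP={cmp_.n_significant_a} "
          f"SV={cmp_.n_significant_b} shared={cmp_.windows_shared}")
    print(f"genes in significant windows: SNP={len(cmp_.genes_a)} "
          f"SV={len(cmp_.genes_b)} shared={len(cmp_.genes_shared)}")


if __name__ == "__main__":
    main()
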
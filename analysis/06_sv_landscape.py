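#!/usr/bin/env python
"""Summarise the SV landscape and find breakpoint hotspots.

Filters the SV VCF (length > 50 bp, missingness <= 0.5, MAF >= 0.01),
tallies types per sample, annotates genomic context (genic / 2 kb
flank / intergenic) and scans 200 kb sliding windows for breakpoint
hotspots (top 5%, merged).
"""

import argparse
import json
from pathlib import Path

from _common import results_dir

from pangenpop import io_filters as io
from pangenpop.sv_analysis import (annotate_context, context_fractions,
                                   hotspot_scan, regions_to_frame, sv_summary)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--bundle", type=Path, default=Path("scratch/simdata"))
    ap.add_argument("--window", type=int, default=200_000)
    ap.add_argument("--step", type=int, default=100_000)
    ap.add_argument("--top", type=float, default=0.05)
    args = ap.parse_args()
    res = results_dir()

    svs, samples = io.read_sv_vcf(args.bundle / "svs.vcf")
    summ = sv_summary(svs, samples)
    summ.per_sample.to_csv(res / "sv_per_sample.tsv", sep="\t")
    print("SV totals:", ", ".join(f"{k}={v}" for k, v in summ.type_totals.items()),
          f"(grand total {summ.grand_total})")
    print(f"per-sample counts {summ.per_sample['count'].min()}-"
          f"{summ.per_sample['count'].max()}; deletion fraction "
          f"~{summ.per_sample['del_fraction'].mean():.2f}")

    genes = io.read_gene_models(args.bundle / "genes.gff3")
    ctx = annotate_context(svs, genes)
    ctx.to_csv(res / "sv_context.tsv", sep="\t", index=False)
    print("context fractions by type:")
    print(context_fractions(ctx).round(3).to_string())

    with open(args.bundle / "truth.json") as fh:
        layout = io.GenomeLayout.from_dict(json.load(fh)["layout"])
    hs = hotspot_scan(svs, layout, args.window, args.step, args.top)
    regions_to_frame(hs).to_csv(res / "sv_hotspots.tsv", sep="\t", index=False)
    io.write_regions_bed([(r.chrom, r.start, r.end) for r in hs.regions],
                         res / "sv_hotspots.bed")
    print(f"{len(hs.regions)} hotspot regions cover "
          f"{hs.genome_fraction:.1%} of the genome and capture "
          f"{hs.capture_fraction:.1%} of SVs")


if __name__ == "__main__":
    main()
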
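#!/usr/bin/env python
"""Generate the synthetic 27-accession study bundle.

Writes gene models (GFF3), exon-coverage fractions, SNP and SV VCFs, a
sweep-score track, the trait design and the planted-truth sidecars, all
under --out (default scratch/simdata).  Every downstream driver reads
this bundle.
"""

import argparse
from pathlib import Path

from _common import add_src_to_path  # noqa: F401

from pangenpop.synthetic_data import SimConfig, simulate_study


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("scratch/simdata"))
    args = ap.parse_args()
    bundle = simulate_study(SimConfig(seed=args.seed), args.out)
    t = bundle.truth
    print(f"wrote study bundle to {args.out}")
    print(f"  genes: {len(t.presence)}  samples: {t.presence.shape[1]}")
    print(f"  planted differential genes: {len(t.differential_genes)}")
    print(f"  planted sweep peaks: {len(t.sweep_intervals)}  "
          f"hotspot clusters: {len(t.hotspot_intervals)}")


if __name__ == "__main__":
    main()
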
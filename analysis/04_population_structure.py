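#!/usr/bin/env python
"""Ordinate the accessions on the binary PAV matrix and build a tree.

PCA on gene-centred presence calls plus an average-linkage tree on
Jaccard distances, written as TSV coordinates and a Newick file.
"""

import argparse
from pathlib import Path

import pandas as pd

from _common import results_dir

from pangenpop.pav import CoverageTable, call_presence
from pangenpop.pav_structure import pav_distance_tree, pav_pca, write_newick


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--bundle", type=Path, default=Path("scratch/simdata"))
    ap.add_argument("--components", type=int, default=5)
    args = ap.parse_args()
    res = results_dir()

    cov = pd.read_csv(args.bundle / "coverage.tsv", sep="\t")
    pav = call_presence(CoverageTable.from_long(cov))

    ords = pav_pca(pav, args.components)
    out = ords.coordinates.copy()
    out.to_csv(res / "pav_pca_coordinates.tsv", sep="\t")
    evr = ", ".join(f"PC{i + 1}={v:.1%}"
                    for i, v in enumerate(ords.explained_variance_ratio))
    print("explained variance:", evr)

    tree = pav_distance_tree(pav)
    tree.distances.to_csv(res / "pav_jaccard_distances.tsv", sep="\t")
    write_newick(tree, res / "pav_tree.nwk")
    print(f"wrote Newick tree over {pav.n_samples} accessions")


if __name__ == "__main__":
    main()
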
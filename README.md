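# pangenpop

Population analysis of a plant pan-genome from presence/absence
variation (PAV), selective-sweep score tracks and structural variants
(SVs), built around the kind of resequencing panel used for tropical
fruit crops: a few dozen accessions mapped against a pan-genome
reference, contrasted across phenotype groups such as cold-tolerant
vs. cold-sensitive or large- vs. small-fruited.

The package is organised as an analysis project: every computation
lives in the library under `src/pangenpop/`, and the numbered drivers
under `analysis/` run the study end-to-end on a bundled synthetic
population with planted ground truth, so each stage has a recovery
test without any external data.

## What it computes

**Gene PAV.** A gene is *present* in an accession when reads at depth
≥ `minCov` (default 2) cover more than `lostCutoff` (default 0.2) of
its exon bases; the library consumes that per-gene, per-sample covered
fraction. Over *n* accessions, genes partition into **core** (present
in all *n*), **dispensable** (2..*n*−1) and **private** (exactly 1).
Pan/core saturation curves over random accession orderings are fitted
with a power law *P(k) = A·k^γ + C* and an exponential decay
*F(k) = A·e^(−k/τ) + C*.

**PAV selection screen.** Per gene, a two-sided Fisher exact test on
the 2×2 presence table between two trait groups, Benjamini–Hochberg
FDR, and a presence-frequency log2 fold change with Haldane–Anscombe
smoothing; significance requires FDR < 0.001 and |log2FC| > 1.
Hypergeometric (upper-tail) term enrichment runs on user-supplied
gene-to-term tables.

**PAV structure.** PCA of accessions on the gene-centred binary
matrix and an average-linkage tree on Jaccard distances
*d(A,B) = 1 − |A∩B|/|A∪B|*, exported as Newick.

**Selective sweeps.** Per-SNP cross-population scores (e.g. XP-CLR)
are averaged in non-overlapping 10 kb windows; windows in the
genome-wide top 5% are signal windows; adjacent signal windows — or
signal windows separated by a single window whose own score is in the
top 10% — merge into sweep regions carrying the maximum member-window
mean; genes attach to regions via ±2 kb flanks.

**Differentiation.** Weir–Cockerham (1984) two-population *F*ST
variance components per site, for SNPs and for SVs-as-biallelic
markers through one code path; 100 kb windows report the arithmetic
mean ("average *F*ST"), the ratio-of-sums (weighted) estimate and
per-group nucleotide diversity π, banded at 0.05 (minimal/moderate)
and 0.15 (moderate/significant).

**SV landscape.** Type totals and per-sample tallies for DEL/DUP/INS
(> 50 bp), genomic-context annotation (genic > 2 kb flank >
intergenic), and breakpoint hotspots: 200 kb windows sliding by
100 kb, ranked by breakpoint count, top 5% merged into hotspot
regions with capture statistics.

**Assays.** Relative electrolyte conductivity REC = R1/R2 × 100%,
MDA content 25.58 × (ΔA + 0.0076)/W (nmol/g), and qPCR fold change
2^−ΔΔCt.

## Worked example

```sh
python analysis/01_simulate_study.py --seed 1   # writes scratch/simdata
python analysis/02_pav_landscape.py
python analysis/06_sv_landscape.py
python analysis/07_differentiation.py
```

prints, for seed 1:

```
pan-genome classification: core=1568, dispensable=360, private=72 (total 2000)
genes per accession: 1640-1775; core fraction ~0.94
SV totals: DEL=1550, DUP=443, INS=5 (grand total 1998)
per-sample counts 1309-1373; deletion fraction ~0.78
9 hotspot regions cover 9.1% of the genome and capture 87.3% of SVs
SNP genome-wide weighted FST: 0.1488 (18685 sites)
```

Reading: of the 2,000 simulated genes, 1,568 are carried by all 27
accessions and 72 by exactly one; each accession carries 1,640–1,775
genes. The SV set is deletion-dominated (~78% per sample), its
breakpoints concentrate so that ~9% of the genome captures ~87% of
SVs, and the genome-wide weighted *F*ST between the two planted trait
groups recovers the simulation's differentiation parameter
(*F* = 0.15) to well within sampling error. The remaining drivers
(03–05) run the frequency screen, the ordination/tree and the sweep
caller the same way; tables land in `results/`.

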
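# Methods

This note documents the models and procedures implemented in
`pangenpop`, the parameters that matter, the synthetic-data generator
behind the tests, and the design decisions taken where conventions
diverge.

## Gene presence/absence

Presence calling consumes a per-gene, per-sample `covered_fraction`:
the fraction of a gene's exon bases covered by at least `min_cov`
reads (default 2). A gene is present when `covered_fraction >
lost_cutoff` (default 0.2), with a *strict* inequality: a gene with
exactly 20% of exon bases covered is absent. Computing depth from
alignments is out of scope; the coverage table is the interface, which
keeps the tested surface format-simple.

Classification over *n* accessions is a disjoint partition by
occurrence count: core = *n*, private = 1, dispensable = 2..*n*−1.
Genes present in zero accessions are dropped with a logged count (they
cannot arise from real calling but can from synthetic edge cases).
The three class counts therefore always sum to the number of genes
observed in at least one accession.

Saturation curves accumulate the union (pan) and intersection (core)
of gene sets over random accession orderings; 100 permutations by
default, seed mandatory. Pan curves are fitted with a power law
*A·k^γ + C* and core curves with an exponential decay
*A·e^(−k/τ) + C* — the conventional forms in pan-genome work; the fit
reports non-convergence in-band rather than raising, and a constant
curve short-circuits to *A* = 0, *C* = the constant.

## Frequency screens

The two-group screen tests each gene's 2×2 presence table
[[a, nA−a], [b, nB−b]] with the two-sided Fisher exact test, defined
as the sum of the probabilities of all tables (at fixed margins) not
exceeding the observed table's probability, with a 1 + 1e−7 relative
tolerance against floating-point ties — the convention scipy also
uses. The implementation vectorises the conditional hypergeometric
distribution per unique column margin; the test suite checks it to
1e−9 against an exact integer-combinatorics enumeration and against
scipy on random tables.

The fold change is computed on smoothed presence frequencies,
log2[(a+0.5)/(nA+1)] − log2[(b+0.5)/(nB+1)] (Haldane–Anscombe), so
zero-presence groups stay finite. Genes fixed identically in both
groups (all present or all absent) are untestable: they are reported
with p = 1 and excluded from the BH adjustment. Significance requires
FDR < 0.001 *and* |log2FC| > 1.

Because the exact test is discrete, its raw p < 0.05 rate under the
null sits *below* the nominal level; the calibration check uses 100
samples per arm, where the attained rate (~0.04) is within 0.05 ± 0.02
while remaining conservative. At small group sizes (e.g. 10 vs 17)
the FDR < 0.001 gate routinely loses individual true positives whose
realised tables are one carrier short; the screen's recall on the
unbalanced 6-vs-21 panel is therefore reported, not asserted.

Term enrichment is the upper-tail hypergeometric test per term with BH
across terms; the background defaults to all genes in the term table,
and the caller supplies the gene-to-term mapping (no ontology
databases are bundled).

## Population structure

Accessions are observations, genes features. The binary matrix is
centred by gene, not scaled (the data are 0/1), and decomposed by SVD;
component signs are fixed by making the largest-magnitude gene loading
positive, so the ordination is fully deterministic. The tree is
average-linkage agglomeration on Jaccard distances between presence
sets, exported as Newick — a distance-based stand-in for maximum
likelihood on binary characters, chosen to keep the artifact free of
external tree-search dependencies while preserving downstream
compatibility. Two accessions with empty presence sets get distance 0
with a warning.

## Sweep-region calling

Score tracks are per-site (chromosome, position, score) tables in
0-based coordinates; windows tile each chromosome from 0 in
non-overlapping 10 kb steps, half-open, and a window's score is the
mean over its sites. Empty windows are excluded from ranking;
chromosome-terminal partial windows are kept and flagged.

"Top q%" is operationalised as score ≥ the k-th largest value with
k = ceil(q·N) over the N non-empty windows, ties included — this keeps
equal-scored windows together and gives |top set| = ceil(q·N) for
distinct values. Signal windows (top 5%) merge when adjacent or when
separated by exactly one window whose *own* mean is in the top 10%;
the alternative reading (the top-10% condition applying to the merged
windows) is vacuous because top-5% membership already implies it, so
the gap-window reading is used. The merged region's score is the
maximum member mean; an empty gap window never bridges. Genes attach
to regions when their span extended by ±2 kb intersects the region's
half-open interval (an extension that exactly touches the boundary
does not count).

## FST and nucleotide diversity

Per-site differentiation uses the Weir–Cockerham (1984) two-population
variance components a (between populations), b (between individuals
within populations) and c (within individuals), computed from the two
groups' sample sizes, allele frequencies and observed heterozygote
frequencies; the estimate is a/(a+b+c). Sites with fewer than two
called genotypes in a group, or monomorphic across both groups, are
skipped with a reason. Negative per-site estimates are retained in
window means (the behaviour of the standard VCF tooling) rather than
clamped.

100 kb windows report both the arithmetic mean of per-site estimates —
the "average FST" that the banding applies to — and the ratio-of-sums
Σa/Σ(a+b+c) (weighted) estimate, because the two differ under
heterogeneous site information and standard tools print both. Bands:
mean FST < 0.05 minimal, 0.05–0.15 moderate, ≥ 0.15 significant;
windows with no usable site are excluded from banding. π per group
is Σ 2p̂(1−p̂)·2n/(2n−1) over sites divided by the *window length in
bp* (not the site count), the per-bp convention.

SVs run through the identical estimator path as SNPs by viewing each
SV as a biallelic marker keyed to its start position; a property test
asserts path equality on identical genotype input. Only two-group
contrasts are supported.

## SV landscape and hotspots

Filtered SVs are DEL/DUP/INS with length strictly greater than 50 bp,
missing-call fraction ≤ 0.5 and MAF ≥ 0.01 (MAF always from
non-missing calls). DEL/DUP lengths derive from END−POS when SVLEN is
absent; INS length comes from SVLEN only and its footprint is the
insertion point.

Context annotation gives each SV exactly one label with precedence
genic > 2 kb flank > intergenic, testing the full interval for DEL/DUP
and the point for INS.

Hotspots: breakpoints are both endpoints of a DEL/DUP and the single
point of an INS; each breakpoint counts in every 200 kb window
(100 kb step) containing it, so an SV spanning two windows contributes
to both. Windows rank by count genome-wide; the top 5% (k-th-largest
threshold, ties included) are hotspot windows, and overlapping or
abutting hotspot windows merge into regions. Capture statistics
report the fraction of SVs with at least one breakpoint inside a
region — each SV is listed in exactly one (the leftmost) region — and
the genome fraction covered.

## Assay calculators

REC = R1/R2 × 100% (R2 > 0 required); MDA = 25.58 × (A532 − A600 +
0.0076)/W in nmol per g fresh weight; relative expression = 2^−ΔΔCt
with ΔΔCt = (Ct_target − Ct_ref)_treatment − (Ct_target −
Ct_ref)_control. Batch helpers average over biological replicates on
the raw quantity *before* transformation; with Ct values the
convention (average before or after exponentiation) is not settled in
practice, and averaging raw Ct first is the package's documented
choice.

## Synthetic study generator

The generator emulates the statistical shape of a 27-accession
resequencing panel in three subgroups (3/3/21) on 11 chromosomes of
2 Mb each (22 Mb total — desk-scale, every stage runs in seconds),
with all randomness drawn from a single seeded generator so outputs
are byte-identical per seed. Defaults:

| parameter | default | rationale |
|---|---|---|
| genes | 2,000 | desk-scale; category mix 76.1/23.1/0.8% mirrors the observed core/dispensable/private proportions of a ~46k-gene pan-genome |
| dispensable frequency law | Beta(0.3, 0.3) | U-shaped occurrence spectrum typical of pan-genomes |
| subgroup markers | 100 genes per minor subgroup, p_in = 0.95 / p_out = 0.05 | makes the planted 3-subgroup structure recoverable from 2 PCs |
| differential genes | 30 at (pA, pB) = (0.95, 0.05) | planted truth for the frequency screen |
| coverage | present ~ Beta(15, 1); absent ~ U(0, 0.1) | high covered fractions for present genes, residual mapping noise below the 0.2 cutoff for absent ones; 0 residual gives the noise-free limit |
| SNPs | 20,000; ancestral p ~ U(0.1, 0.9); Balding–Nichols F = 0.15 between trait groups; 1% missing | supplies the FST recovery surface, E[FST] ≈ F |
| sweep score track | per-SNP Exp(1) background; 8 peaks × 137.5 kb, ×10 elevation | peaks jointly occupy 5% of the genome, the same share as the top-5% window calling that must recover them |
| SVs | 1,550 DEL / 445 DUP / 5 INS; lengths lognormal, min 60 bp | deletion-dominated mix (~78% DEL) at the proportions of the emulated panel |
| hotspot clusters | 10 × 100 kb holding 85% of SVs, centred on distinct 200 kb lattice slots | non-overlapping clusters that each project onto a single dominant scan window, keeping the planted truth identifiable by the stated scan geometry |

What the generator does *not* emulate: linkage disequilibrium and
recombination (loci are unlinked), read-level error (coverage arrives
as fractions, not alignments), gene-length or GC coverage bias,
multi-allelic variation, and relatedness beyond the two-level
group/subgroup structure. Passing recovery tests therefore
demonstrate the *algorithms* recover planted structure under the
stated noise, not that real panels will behave as cleanly.

The trait design contrasts the two minor subgroups (6 accessions,
"cold_tolerant") against the main panel (21, "cold_sensitive"),
echoing the emulated study's unbalanced contrast.

## Numerical choices

- Coordinates: 0-based half-open everywhere internally; GFF3/VCF
  converted at the boundary. Score-track TSVs are 0-based.
- The SNP MAF default is 0.05. The emulated pipeline's printed filter
  string ("--maf 0.5") contradicts its stated intent (removing
  MAF < 5%); the intent wins, and the threshold is overridable.
- Missing genotypes are `./.`; half-missing calls count as missing.
- Top-percentile thresholds use the k-th largest value with
  k = ceil(fraction·N); ties at the cut are included everywhere
  (sweep windows, hotspot windows).
- Per-accession gene totals count every present gene, whether on the
  reference or on novel sequence.
- Saturation fits start from data-driven initial values and cap
  `curve_fit` at 20,000 evaluations.
- Fisher tie tolerance 1 + 1e−7, matching scipy's convention.

## Problem sizes

The default test suite and the acceptance script run entirely on the
generator's defaults (2,000 genes, 20,000 SNPs, ~2,000 SVs, 27
accessions, 22 Mb genome) and on small fixtures; the full suite
completes in well under a minute of compute per module, with the
exhaustive Fisher-table check (all group margins to 30) the single
largest item.

## Known limitations

- Only two-population FST; no hierarchical or multi-group estimators.
- The distance tree is not a likelihood phylogeny; no bootstrap
  supports are computed.
- XP-CLR (or any sweep statistic) is consumed, never computed.
- Enrichment is term-table-driven; no ontology topology awareness.
- The hotspot scan's uniform-background behaviour depends on the
  window/step ratio (2 by default); other ratios are supported but the
  capture bands documented here were characterised at the default.
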
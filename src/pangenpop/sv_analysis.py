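"""Structural-variant landscape statistics and hotspot detection.

Summaries of the filtered SV set (type totals, per-sample tallies),
genomic-context annotation with genic > 2 kb-flank > intergenic
precedence, and sliding-window breakpoint-density hotspot scans
(200 kb windows, 100 kb steps, top 5% by breakpoint count, adjacent
hotspot windows merged into regions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_filters import SV_TYPES, GeneModel, GenomeLayout, SvRecord
from .sweeps import top_fraction_threshold


@dataclass
class SvSummary:
    type_totals: dict[str, int]
    grand_total: int
    per_sample: pd.DataFrame  # index sample: count, del_count, del_fraction


def sv_summary(svs: list[SvRecord], samples: list[str]) -> SvSummary:
    """Type totals and per-sample SV counts.

    A sample carries an SV when its genotype holds at least one SV
    allele (dosage 1 or 2); missing calls do not count.
    """
    type_totals = {t: 0 for t in SV_TYPES}
    for sv in svs:
        type_totals[sv.type] += 1
    geno = (np.array([s.genotypes for s in svs], dtype=np.int8)
            if svs else np.empty((0, len(samples)), dtype=np.int8))
    carried = (geno == 1) | (geno == 2)
    types = np.array([s.type for s in svs]) if svs else np.empty(0, dtype=object)
    counts = carried.sum(axis=0)
    del_counts = carried[types == "DEL"].sum(axis=0) if len(types) else counts * 0
    per_sample = pd.DataFrame({
        "count": counts,
        "del_count": del_counts,
        "del_fraction": np.divide(del_counts, counts,
                                  out=np.zeros(len(samples), dtype=float),
                                  where=counts > 0),
    }, index=pd.Index(samples, name="sample"))
    return SvSummary(type_totals, sum(type_totals.values()), per_sample)


def annotate_context(svs: list[SvRecord], genes: list[GeneModel],
                     flank_bp: int = 2_000) -> pd.DataFrame:
    """Assign each SV a single genomic context with fixed precedence.

    genic when the SV footprint (full interval for DEL/DUP, insertion
    point for INS) overlaps any gene span; otherwise flank_2kb when it
    overlaps a 2 kb region immediately up- or downstream of a gene;
    otherwise intergenic.  Returns sv_id, type, context and the
    justifying gene(s).
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    rows = []
    for sv in svs:
        s, e = sv.interval
        genic_hits, flank_hits = [], []
        for g in by_chrom.get(sv.chrom, ()):
            if g.start < e and s < g.end:
                genic_hits.append(g.gene_id)
            elif (max(g.start - flank_bp, 0) < e and s < g.start) or \
                 (g.end < e and s < g.end + flank_bp):
                flank_hits.append(g.gene_id)
        if genic_hits:
            ctx, hits = "genic", genic_hits
        elif flank_hits:
            ctx, hits = "flank_2kb", flank_hits
        else:
            ctx, hits = "intergenic", []
        rows.append((sv.sv_id, sv.type, ctx, ",".join(hits)))
    return pd.DataFrame(rows, columns=["sv_id", "type", "context", "genes"])


def context_fractions(context: pd.DataFrame) -> pd.DataFrame:
    """Per-SV-type fractions of each genomic context."""
    tab = context.groupby(["type", "context"]).size().unstack(fill_value=0)
    return tab.div(tab.sum(axis=1), axis=0)


@dataclass
class HotspotRegion:
    chrom: str
    start: int
    end: int
    n_windows: int
    breakpoint_count: int
    sv_ids: tuple[str, ...] = ()


@dataclass
class HotspotResult:
    regions: list[HotspotRegion]
    window_counts: pd.DataFrame      # all windows with breakpoint counts
    threshold: float                 # count delimiting the hotspot set
    capture_fraction: float          # SVs with >=1 breakpoint in a region
    genome_fraction: float           # bp covered by regions / genome bp


def hotspot_scan(svs: list[SvRecord], layout: GenomeLayout,
                 window_bp: int = 200_000, step_bp: int = 100_000,
                 top_fraction: float = 0.05) -> HotspotResult:
    """Sliding-window SV-breakpoint hotspot scan with region merging.

    Breakpoints are both endpoints of a DEL/DUP and the single insertion
    point of an INS; a breakpoint is counted in every window containing
    it.  Windows are ranked genome-wide by breakpoint count and the top
    ``top_fraction`` (ties at the cut included) become hotspot windows;
    overlapping or abutting hotspot windows merge into regions.  Each SV
    with a breakpoint inside some region is listed in exactly one
    (the leftmost such) region.
    """
    if step_bp > window_bp:
        raise ValueError("window must be at least as large as the step")
    if window_bp % step_bp:
        raise ValueError("step must divide the window size evenly")

    # window table
    rows = []
    for chrom in layout.chromosomes:
        clen = layout.length_of(chrom)
        for s in range(0, clen, step_bp):
            rows.append((chrom, s, min(s + window_bp, clen)))
    win = pd.DataFrame(rows, columns=["chrom", "start", "end"])

    # breakpoint counts per window
    bp_by_chrom: dict[str, list[int]] = {}
    for sv in svs:
        bp_by_chrom.setdefault(sv.chrom, []).extend(sv.breakpoints)
    counts = np.zeros(len(win), dtype=np.int64)
    for chrom, sub_idx in win.groupby("chrom").groups.items():
        pts = np.sort(np.asarray(bp_by_chrom.get(chrom, []), dtype=np.int64))
        if len(pts) == 0:
            continue
        sub = win.loc[sub_idx]
        lo = np.searchsorted(pts, sub["start"].to_numpy(), side="left")
        hi = np.searchsorted(pts, sub["end"].to_numpy(), side="left")
        counts[np.asarray(sub_idx)] = hi - lo
    win["breakpoints"] = counts

    threshold = top_fraction_threshold(counts, top_fraction) if len(win) else 0.0
    hot = win[win["breakpoints"] >= threshold].sort_values(
        ["chrom", "start"], kind="mergesort")

    # merge overlapping/abutting hotspot windows
    regions: list[HotspotRegion] = []
    for chrom, sub in hot.groupby("chrom", sort=False):
        cur = None
        for r in sub.itertuples():
            if cur is not None and r.start <= cur[1]:
                cur = (cur[0], max(cur[1], r.end), cur[2] + 1)
            else:
                if cur is not None:
                    regions.append(HotspotRegion(chrom, cur[0], cur[1], cur[2], 0))
                cur = (r.start, r.end, 1)
        if cur is not None:
            regions.append(HotspotRegion(chrom, cur[0], cur[1], cur[2], 0))
    regions.sort(key=lambda r: (r.chrom, r.start))

    # assign each SV to the leftmost region containing one of its breakpoints
    captured: dict[int, list[str]] = {i: [] for i in range(len(regions))}
    bp_counts = [0] * len(regions)
    n_captured_svs = 0
    region_index: dict[str, list[tuple[int, int, int]]] = {}
    for i, r in enumerate(regions):
        region_index.setdefault(r.chrom, []).append((r.start, r.end, i))
    for sv in svs:
        hit_region = None
        for p in sv.breakpoints:
            for (s, e, i) in region_index.get(sv.chrom, ()):
                if s <= p < e:
                    bp_counts[i] += 1
                    if hit_region is None:
                        hit_region = i
        if hit_region is not None:
            captured[hit_region].append(sv.sv_id)
            n_captured_svs += 1
    regions = [HotspotRegion(r.chrom, r.start, r.end, r.n_windows,
                             bp_counts[i], tuple(captured[i]))
               for i, r in enumerate(regions)]

    genome_bp = layout.total_length
    covered = sum(r.end - r.start for r in regions)
    return HotspotResult(
        regions=regions,
        window_counts=win,
        threshold=float(threshold),
        capture_fraction=(n_captured_svs / len(svs)) if svs else 0.0,
        genome_fraction=covered / genome_bp,
    )


def regions_to_frame(result: HotspotResult) -> pd.DataFrame:
    return pd.DataFrame([{
        "chrom": r.chrom, "start": r.start, "end": r.end,
        "n_windows": r.n_windows, "breakpoints": r.breakpoint_count,
        "n_svs": len(r.sv_ids),
    } for r in result.regions])
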
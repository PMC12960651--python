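"""Selective-sweep region calling from per-site score tracks.

Consumes a per-SNP cross-population score track (XP-CLR or any sweep
statistic), averages scores in non-overlapping windows (10 kb default),
calls windows in the top 5% genome-wide as strong signals, merges
adjacent signal windows — tolerating a single intervening window whose
own score sits in the top 10% — and assigns the maximum member-window
mean to each merged region.  Genes are attached to regions through
their spans extended by +-2 kb flanks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_filters import GeneModel, GenomeLayout


def window_scores(track: pd.DataFrame, layout: GenomeLayout,
                  window_bp: int = 10_000) -> pd.DataFrame:
    """Mean score in non-overlapping windows tiling each chromosome from 0.

    ``track`` has columns chrom, pos (0-based), score; a site at position
    p falls in window [p // w * w, p // w * w + w).  Returns one row per
    non-empty window with columns chrom, start, end, window_index,
    n_sites, mean_score, terminal (True for a chromosome's partial last
    window).  Sites beyond the chromosome length raise an error naming
    the offending site.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    rows = []
    for chrom, sub in track.groupby("chrom", sort=False):
        if chrom not in layout:
            raise ValueError(f"score track chromosome {chrom!r} not in layout")
        clen = layout.length_of(chrom)
        pos = sub["pos"].to_numpy()
        bad = (pos >= clen) | (pos < 0)
        if bad.any():
            p = int(pos[bad][0])
            raise ValueError(f"site {chrom}:{p} beyond chromosome length {clen}")
        widx = pos // window_bp
        grouped = pd.DataFrame({"w": widx, "score": sub["score"].to_numpy()}) \
            .groupby("w")["score"].agg(["size", "mean"])
        n_windows = math.ceil(clen / window_bp)
        for w, (n_sites, mean) in grouped.iterrows():
            start = int(w) * window_bp
            end = min(start + window_bp, clen)
            rows.append((chrom, start, end, int(w), int(n_sites), float(mean),
                         int(w) == n_windows - 1 and end - start < window_bp))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "window_index",
                                      "n_sites", "mean_score", "terminal"])
    out = out.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    if len(out):
        out["percentile_rank"] = out["mean_score"].rank(pct=True)
    else:
        out["percentile_rank"] = pd.Series(dtype=float)
    return out


def top_fraction_threshold(values: np.ndarray, fraction: float) -> float:
    """Score threshold delimiting the top ``fraction`` of values.

    The threshold is the k-th largest value with k = ceil(fraction * N);
    everything >= the threshold is in the top set, so ties at the cut are
    included.
    """
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise ValueError("no values to rank")
    k = max(1, math.ceil(fraction * len(values)))
    return float(np.partition(values, -k)[-k])


@dataclass
class SweepRegion:
    chrom: str
    start: int
    end: int
    score: float          # max of member-window mean scores
    n_windows: int        # number of top-signal member windows
    window_starts: tuple[int, ...] = ()
    genes: tuple[str, ...] = ()


def call_and_merge(windows: pd.DataFrame, top_signal_fraction: float = 0.05,
                   gap_fraction: float = 0.10,
                   window_bp: int | None = None) -> list[SweepRegion]:
    """Call top-signal windows and merge them into sweep regions.

    Windows whose mean score lies in the genome-wide top
    ``top_signal_fraction`` are signal windows.  Two signal windows on
    the same chromosome merge when adjacent, or when separated by
    exactly one window whose own mean score lies in the top
    ``gap_fraction``; each region carries the maximum member mean.
    ``window_bp`` defaults to the modal window width in the input.
    """
    if windows.empty:
        return []
    if len(windows) < 20:
        warnings.warn("fewer than 20 non-empty windows; top-percent "
                      "thresholds are degenerate")
    means = windows["mean_score"].to_numpy()
    t_sig = top_fraction_threshold(means, top_signal_fraction)
    t_gap = top_fraction_threshold(means, gap_fraction)
    if window_bp is None:
        widths = (windows["end"] - windows["start"]).to_numpy()
        window_bp = int(pd.Series(widths).mode().iloc[0])

    regions: list[SweepRegion] = []
    for chrom, sub in windows.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        idx = (sub["start"].to_numpy() // window_bp)
        mean = sub["mean_score"].to_numpy()
        end_ = sub["end"].to_numpy()
        start_ = sub["start"].to_numpy()
        by_index = dict(zip(idx, mean))
        sig_positions = np.flatnonzero(mean >= t_sig)
        if len(sig_positions) == 0:
            continue
        run = [sig_positions[0]]
        for p in sig_positions[1:]:
            gap = idx[p] - idx[run[-1]]
            if gap == 1:
                run.append(p)
            elif gap == 2 and by_index.get(idx[run[-1]] + 1, -np.inf) >= t_gap:
                run.append(p)
            else:
                regions.append(_finish_run(chrom, run, start_, end_, mean))
                run = [p]
        regions.append(_finish_run(chrom, run, start_, end_, mean))
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def _finish_run(chrom, run, starts, ends, means) -> SweepRegion:
    member_means = [means[p] for p in run]
    return SweepRegion(
        chrom=chrom,
        start=int(starts[run[0]]),
        end=int(ends[run[-1]]),
        score=float(max(member_means)),
        n_windows=len(run),
        window_starts=tuple(int(starts[p]) for p in run),
    )


def genes_in_regions(regions: list[SweepRegion], genes: list[GeneModel],
                     flank_bp: int = 2_000) -> list[SweepRegion]:
    """Attach genes to sweep regions via +-flank-extended span intersection.

    A gene belongs to a region when [gene.start - flank, gene.end + flank)
    overlaps the region's half-open interval; a gene may appear in
    several regions.  Returns new region objects with ``genes`` filled.
    """
    out = []
    for r in regions:
        hits = tuple(
            g.gene_id for g in genes
            if g.chrom == r.chrom
            and g.start - flank_bp < r.end and r.start < g.end + flank_bp
        )
        out.append(SweepRegion(r.chrom, r.start, r.end, r.score, r.n_windows,
                               r.window_starts, hits))
    return out


def regions_to_frame(regions: list[SweepRegion]) -> pd.DataFrame:
    return pd.DataFrame([{
        "chrom": r.chrom, "start": r.start, "end": r.end,
        "score": r.score, "n_windows": r.n_windows,
        "genes": ",".join(r.genes),
    } for r in regions])
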
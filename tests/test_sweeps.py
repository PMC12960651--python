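"""Score windowing, top-percentile calling and gap-tolerant merging."""

import math

import numpy as np
import pandas as pd
import pytest

from pangenpop.io_filters import GeneModel, GenomeLayout
from pangenpop.sweeps import (SweepRegion, call_and_merge, genes_in_regions,
                              top_fraction_threshold, window_scores)


# ---------------------------------------------------------------------------
# literal enumeration oracle for the call-and-merge rule
# ---------------------------------------------------------------------------

def merge_oracle(means_by_index, top=0.05, gap=0.10):
    """Brute-force transcription of the merge rule on one chromosome.

    means_by_index: {window_index: mean score} for non-empty windows.
    Top sets are 'score >= k-th largest with k = ceil(frac * N)'.  Signal
    windows merge when adjacent or separated by exactly one window whose
    own score is in the top-gap set.
    """
    vals = sorted(means_by_index.values(), reverse=True)
    n = len(vals)

    def thresh(frac):
        return vals[max(1, math.ceil(frac * n)) - 1]

    t5, t10 = thresh(top), thresh(gap)
    sig = sorted(i for i, v in means_by_index.items() if v >= t5)
    regions = []
    cur = None
    for i in sig:
        if cur is None:
            cur = [i]
        else:
            last = cur[-1]
            if i - last == 1:
                cur.append(i)
            elif i - last == 2 and means_by_index.get(last + 1, -np.inf) >= t10:
                cur.append(i)
            else:
                regions.append(cur)
                cur = [i]
    if cur:
        regions.append(cur)
    return [(r[0], r[-1], max(means_by_index[i] for i in r), len(r))
            for r in regions]


def _windows_frame(means_by_index, window_bp=10_000, chrom="chr1"):
    rows = [(chrom, i * window_bp, (i + 1) * window_bp, i, 5, m, False)
            for i, m in sorted(means_by_index.items())]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "window_index",
                                       "n_sites", "mean_score", "terminal"])


# ---------------------------------------------------------------------------
# window_scores
# ---------------------------------------------------------------------------

def test_window_mean_arithmetic(toy_layout):
    track = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [1_000, 5_000],
                          "score": [10.0, 20.0]})
    w = window_scores(track, toy_layout, 10_000)
    assert len(w) == 1
    assert w["mean_score"].iloc[0] == pytest.approx(15.0)
    assert (w["start"].iloc[0], w["end"].iloc[0]) == (0, 10_000)


def test_half_open_boundary(toy_layout):
    track = pd.DataFrame({"chrom": ["chr1"], "pos": [10_000], "score": [1.0]})
    w = window_scores(track, toy_layout, 10_000)
    assert w["start"].iloc[0] == 10_000  # second window, not the first


def test_site_beyond_chromosome_errors(toy_layout):
    track = pd.DataFrame({"chrom": ["chr2"], "pos": [1_000_000], "score": [1.0]})
    with pytest.raises(ValueError, match="chr2:1000000"):
        window_scores(track, toy_layout, 10_000)


def test_window_means_match_grouping_oracle(toy_layout):
    rng = np.random.default_rng(5)
    n = 1000
    chroms = np.where(rng.random(n) < 0.6, "chr1", "chr2")
    pos = np.array([rng.integers(0, toy_layout.length_of(c)) for c in chroms])
    track = pd.DataFrame({"chrom": chroms, "pos": pos,
                          "score": rng.exponential(1, n)}) \
        .sort_values(["chrom", "pos"]).reset_index(drop=True)
    w = window_scores(track, toy_layout, 10_000)
    # brute-force regrouping
    expected = {}
    for c, p, s in track.itertuples(index=False):
        key = (c, p // 10_000)
        expected.setdefault(key, []).append(s)
    assert len(w) == len(expected)
    for row in w.itertuples():
        vals = expected[(row.chrom, row.start // 10_000)]
        assert row.n_sites == len(vals)
        assert row.mean_score == pytest.approx(np.mean(vals))


# ---------------------------------------------------------------------------
# thresholds and merging
# ---------------------------------------------------------------------------

def test_top_fraction_counts():
    """|top set| equals ceil(fraction * N) for distinct values."""
    rng = np.random.default_rng(0)
    for n in (20, 100, 101, 137):
        vals = rng.permutation(n).astype(float)
        for frac in (0.05, 0.10):
            t = top_fraction_threshold(vals, frac)
            assert (vals >= t).sum() == math.ceil(frac * n)


def test_ties_included_at_cut():
    vals = np.array([5.0] * 10 + [1.0] * 90)
    t = top_fraction_threshold(vals, 0.05)
    assert (vals >= t).sum() == 10  # all tied windows kept


def test_single_isolated_signal_window():
    means = {i: 1.0 + i * 1e-4 for i in range(100)}
    means[50] = 100.0
    regions = call_and_merge(_windows_frame(means), 0.01, 0.02)
    top = [r for r in regions if r.score == 100.0]
    assert len(top) == 1 and top[0].n_windows == 1
    assert (top[0].start, top[0].end) == (500_000, 510_000)


def test_gap_window_in_top10_bridges():
    """Signal windows at 7 and 9 bridge through a top-10% window at 8."""
    means = {i: float(i) / 1000 for i in range(100)}
    means[7], means[9] = 100.0, 90.0
    means[20], means[40], means[60] = 80.0, 70.0, 60.0  # fill the top-5% set
    means[8] = 50.0          # in top 10% but not top 5%
    regions = call_and_merge(_windows_frame(means))
    hit = [r for r in regions if r.start == 70_000]
    assert len(hit) == 1
    assert hit[0].end == 100_000
    assert hit[0].score == pytest.approx(100.0)
    assert hit[0].n_windows == 2


def test_two_window_gap_never_bridges():
    means = {i: float(i) / 1000 for i in range(100)}
    means[7], means[10] = 100.0, 90.0
    means[20], means[40], means[60] = 80.0, 70.0, 60.0  # fill the top-5% set
    means[8] = means[9] = 50.0   # top-10% gap windows, but the gap is two wide
    regions = call_and_merge(_windows_frame(means))
    starts = {r.start for r in regions if r.score >= 90}
    assert {70_000, 100_000} <= starts


def test_low_gap_window_does_not_bridge():
    means = {i: 1.0 + i * 1e-5 for i in range(200)}
    means[7], means[9] = 100.0, 90.0
    means[8] = 0.5           # below the top-10% cut
    regions = call_and_merge(_windows_frame(means))
    starts = {r.start for r in regions if r.score >= 90}
    assert {70_000, 90_000} <= starts


def test_merge_matches_enumeration_oracle_random():
    rng = np.random.default_rng(17)
    for _ in range(100):
        n = 200
        means = dict(enumerate(np.round(rng.exponential(1, n), 2)))
        if rng.random() < 0.3:  # punch holes: empty windows
            for i in rng.integers(0, n, 10):
                means.pop(int(i), None)
        got = call_and_merge(_windows_frame(means), 0.05, 0.10)
        expected = merge_oracle(means)
        assert [(r.start // 10_000, r.end // 10_000 - 1, r.score, r.n_windows)
                for r in got] == \
            [(s, e, pytest.approx(sc), nw) for s, e, sc, nw in expected]


def test_merge_idempotent():
    rng = np.random.default_rng(23)
    means = dict(enumerate(rng.exponential(1, 300)))
    regions = call_and_merge(_windows_frame(means))
    # re-run on the member windows only: every region survives unchanged
    member = {}
    for r in regions:
        for s in r.window_starts:
            member[s // 10_000] = means[s // 10_000]
    again = call_and_merge(_windows_frame(member), top_signal_fraction=1.0,
                           gap_fraction=1.0)
    # with all member windows signal, maximal runs re-form the same spans
    got = {(r.chrom, r.start) for r in again}
    want = set()
    for r in regions:
        want.add((r.chrom, r.window_starts[0]))
    assert want <= got


def test_few_windows_warns():
    means = dict(enumerate(np.arange(5, dtype=float)))
    with pytest.warns(UserWarning, match="fewer than 20"):
        call_and_merge(_windows_frame(means))


# ---------------------------------------------------------------------------
# gene assignment
# ---------------------------------------------------------------------------

def _gene(gid, start, end, chrom="chr1"):
    return GeneModel(gid, chrom, "+", start, end, ((start, end),))


def test_gene_flank_boundaries():
    region = SweepRegion("chr1", 50_000, 60_000, 1.0, 1)
    near = _gene("near", 40_000, 48_500)    # ends 1.5 kb before the region
    touch = _gene("touch", 40_000, 48_000)  # exactly 2 kb before: excluded
    (r,) = genes_in_regions([region], [near, touch], flank_bp=2_000)
    assert r.genes == ("near",)


def test_gene_assignment_matches_quadratic_oracle(toy_layout):
    rng = np.random.default_rng(31)
    genes = []
    for i in range(200):
        chrom = "chr1" if rng.random() < 0.5 else "chr2"
        start = int(rng.integers(0, toy_layout.length_of(chrom) - 6000))
        genes.append(_gene(f"g{i}", start, start + int(rng.integers(500, 5000)),
                           chrom))
    regions = []
    for i in range(10):
        chrom = "chr1" if i < 6 else "chr2"
        start = int(rng.integers(0, toy_layout.length_of(chrom) - 60_000))
        regions.append(SweepRegion(chrom, start, start + 50_000, 1.0, 5))
    out = genes_in_regions(regions, genes, flank_bp=2_000)
    for r in out:
        expected = {g.gene_id for g in genes
                    if g.chrom == r.chrom
                    and max(g.start - 2_000, r.start) < min(g.end + 2_000, r.end)}
        assert set(r.genes) == expected
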
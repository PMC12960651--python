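"""Gene-frequency selection screens on the presence/absence matrix.

Two-group contrasts use Fisher's exact test on the 2x2 presence table
per gene with Benjamini-Hochberg FDR control, gated on the log2 fold
change of presence frequencies; term enrichment uses the upper-tail
hypergeometric test on user-supplied gene-to-term tables.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_filters import GroupDesign
from .pav import PavMatrix

logger = logging.getLogger(__name__)

#: relative tolerance when comparing table probabilities for the
#: two-sided Fisher rule "sum all tables at most as probable as observed"
_REL_TOL = 1 + 1e-7


def fisher_two_sided_p(a: np.ndarray, b: np.ndarray, n_a: int, n_b: int) -> np.ndarray:
    """Vectorised two-sided Fisher exact p for tables [[a, nA-a], [b, nB-b]].

    Conditional on all margins, the count a follows a hypergeometric
    distribution; the two-sided p sums the probabilities of all tables
    whose probability does not exceed the observed one (with a small
    relative tolerance against floating-point ties).
    """
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    out = np.empty(a.shape, dtype=float)
    total = n_a + n_b
    for K in np.unique(a + b):
        lo, hi = max(0, K - n_b), min(n_a, K)
        support = np.arange(lo, hi + 1)
        pmf = hypergeom.pmf(support, total, K, n_a)
        mask = (a + b) == K
        obs = pmf[a[mask] - lo]
        out[mask] = np.where(
            pmf[None, :] <= obs[:, None] * _REL_TOL, pmf[None, :], 0.0
        ).sum(axis=1)
    return np.minimum(out, 1.0)


def log2_fold_change(a: np.ndarray, b: np.ndarray, n_a: int, n_b: int) -> np.ndarray:
    """log2 ratio of presence frequencies with Haldane-Anscombe smoothing.

    Frequencies are (count + 0.5)/(n + 1), which keeps groups with zero
    (or full) presence finite.
    """
    return np.log2((np.asarray(a) + 0.5) / (n_a + 1)) - \
        np.log2((np.asarray(b) + 0.5) / (n_b + 1))


def fisher_presence_test(pav: PavMatrix, design: GroupDesign,
                         group_a: str, group_b: str,
                         fdr_cutoff: float = 0.001,
                         lfc_cutoff: float = 1.0) -> pd.DataFrame:
    """Per-gene two-group presence-frequency contrast.

    Returns one row per gene with the 2x2 counts, the two-sided Fisher
    p, the BH-adjusted FDR, the smoothed log2 fold change, and the
    combined significance call (fdr < fdr_cutoff and |lfc| > lfc_cutoff).

    Genes fixed identically in every sample of both groups (all present
    or all absent) are untestable: they are reported with p = 1 and are
    excluded from the BH adjustment (fdr = 1), with a logged count.
    """
    samples_a, samples_b = design.contrast(group_a, group_b)
    missing = [s for s in samples_a + samples_b if s not in pav.presence.columns]
    if missing:
        raise ValueError(f"design samples absent from PAV matrix: {missing}")
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("each contrast group needs at least 2 samples")

    n_a, n_b = len(samples_a), len(samples_b)
    a = pav.presence[samples_a].sum(axis=1).to_numpy()
    b = pav.presence[samples_b].sum(axis=1).to_numpy()

    fixed = ((a == n_a) & (b == n_b)) | ((a == 0) & (b == 0))
    if fixed.any():
        logger.info("fisher_presence_test: %d genes fixed in both groups "
                    "excluded from BH", int(fixed.sum()))

    p = np.ones(len(a))
    p[~fixed] = fisher_two_sided_p(a[~fixed], b[~fixed], n_a, n_b)
    fdr = np.ones(len(a))
    if (~fixed).sum():
        fdr[~fixed] = multipletests(p[~fixed], method="fdr_bh")[1]
    lfc = log2_fold_change(a, b, n_a, n_b)
    sig = (fdr < fdr_cutoff) & (np.abs(lfc) > lfc_cutoff) & ~fixed

    return pd.DataFrame({
        "gene": pav.presence.index,
        "count_a": a, "n_a": n_a,
        "count_b": b, "n_b": n_b,
        "p_value": p, "fdr": fdr,
        "log2_fold_change": lfc,
        "tested": ~fixed,
        "significant": sig,
    }).set_index("gene")


def hypergeometric_enrichment(gene_set, term_table: pd.DataFrame,
                              background=None) -> pd.DataFrame:
    """Upper-tail hypergeometric term enrichment with BH adjustment.

    ``term_table`` maps genes to terms (columns: gene, term, optionally
    term_name); ``background`` defaults to all genes in the term table.
    For each term with m annotated background genes, the p-value is the
    probability of observing at least k hits when drawing |gene_set|
    genes from the background of size M.
    """
    if background is None:
        background = term_table["gene"].unique()
    background = set(background)
    if not background:
        raise ValueError("empty background")
    gene_set = set(gene_set)
    if not gene_set <= background:
        raise ValueError("gene_set must be a subset of the background")

    tt = term_table[term_table["gene"].isin(background)]
    names = {}
    if "term_name" in tt.columns:
        names = dict(zip(tt["term"], tt["term_name"]))
    M, K = len(background), len(gene_set)
    rows = []
    for term, sub in tt.groupby("term"):
        genes = set(sub["gene"])
        m = len(genes)
        k = len(genes & gene_set)
        p = float(hypergeom.sf(k - 1, M, m, K))
        rows.append((term, names.get(term, ""), k, K, m, M, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["term", "term_name", "hits", "set_size",
                                      "background_hits", "background_size", "p_value"])
    if len(out):
        out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
    else:
        out["fdr"] = pd.Series(dtype=float)
    return out.sort_values("p_value", kind="mergesort").reset_index(drop=True)
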
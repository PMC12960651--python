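"""Gene presence/absence calling, pan-genome classification and saturation.

A gene is called present in an accession when short reads cover more
than a cutoff fraction of its exon bases at a minimum depth (the
SGSGeneLoss-style rule; depth computation happens upstream and arrives
here as a per-gene per-sample ``covered_fraction``).  Presence counts
over n accessions partition genes into core (all n), dispensable
(2..n-1) and private (exactly 1) classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

CATEGORIES = ("core", "dispensable", "private")


@dataclass
class CoverageTable:
    """Per-gene per-sample fraction of exon bases covered at >= min_cov reads."""

    fractions: pd.DataFrame  # genes x samples, float in [0,1]
    min_cov: int = 2

    def __post_init__(self):
        vals = self.fractions.to_numpy()
        if np.isnan(vals).any():
            raise ValueError("coverage table must be complete (no NaN)")
        if (vals < 0).any() or (vals > 1).any():
            raise ValueError("covered_fraction values must lie in [0,1]")

    @classmethod
    def from_long(cls, df: pd.DataFrame, min_cov: int = 2) -> "CoverageTable":
        """Build from a long TSV-style frame (gene, sample, covered_fraction)."""
        wide = df.pivot(index="gene", columns="sample", values="covered_fraction")
        if wide.isna().any().any():
            raise ValueError("coverage table incomplete: missing gene x sample cells")
        return cls(wide, min_cov=min_cov)


@dataclass
class PavMatrix:
    """Binary genes x samples presence matrix, optionally categorised."""

    presence: pd.DataFrame  # genes x samples, int8 0/1
    categories: pd.Series | None = None  # per gene, in CATEGORIES

    @property
    def samples(self) -> list[str]:
        return list(self.presence.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.presence.index)

    @property
    def n_samples(self) -> int:
        return self.presence.shape[1]

    @property
    def occurrence(self) -> pd.Series:
        """Number of accessions carrying each gene (row sums)."""
        return self.presence.sum(axis=1)

    def category_counts(self) -> pd.Series:
        if self.categories is None:
            raise ValueError("matrix not categorised; run classify_genes first")
        return self.categories.value_counts().reindex(CATEGORIES, fill_value=0)

    def to_frame(self) -> pd.DataFrame:
        out = self.presence.copy()
        out.insert(0, "occurrence", self.occurrence)
        if self.categories is not None:
            out.insert(0, "category", self.categories)
        return out


def call_presence(coverage: CoverageTable, lost_cutoff: float = 0.2) -> PavMatrix:
    """Call a gene present where covered_fraction strictly exceeds lost_cutoff.

    The strict inequality means a gene with exactly ``lost_cutoff`` of its
    exon bases covered is called absent.
    """
    if not 0 <= lost_cutoff < 1:
        raise ValueError("lost_cutoff must be in [0,1)")
    present = (coverage.fractions.to_numpy() > lost_cutoff).astype(np.int8)
    return PavMatrix(pd.DataFrame(present, index=coverage.fractions.index,
                                  columns=coverage.fractions.columns))


def classify_genes(pav: PavMatrix) -> PavMatrix:
    """Partition genes into core / dispensable / private by occurrence count.

    core: present in all n accessions; private: present in exactly one;
    dispensable: present in 2..n-1.  Genes present in zero accessions are
    dropped (with a logged count) — they carry no information downstream.
    """
    n = pav.n_samples
    if n < 2:
        raise ValueError("classification requires at least 2 samples")
    counts = pav.occurrence
    zero = counts == 0
    if zero.any():
        logger.info("classify_genes: dropping %d genes absent in all samples",
                    int(zero.sum()))
    presence = pav.presence.loc[~zero]
    counts = counts.loc[~zero]
    cats = pd.Series(
        np.select([counts == n, counts == 1], ["core", "private"], "dispensable"),
        index=presence.index, name="category")
    return PavMatrix(presence, cats)


def accession_gene_counts(pav: PavMatrix) -> pd.DataFrame:
    """Per-accession gene totals broken down by category.

    Returns one row per sample with total, per-category counts and
    per-category fractions (fractions sum to 1 per sample).
    """
    if pav.categories is None:
        raise ValueError("matrix must be categorised")
    rows = {}
    for cat in CATEGORIES:
        sub = pav.presence.loc[pav.categories == cat]
        rows[cat] = sub.sum(axis=0)
    out = pd.DataFrame(rows)
    out.insert(0, "total", out.sum(axis=1))
    for cat in CATEGORIES:
        out[f"{cat}_fraction"] = out[cat] / out["total"]
    out.index.name = "sample"
    return out


@dataclass
class SaturationCurve:
    """Pan/core gene counts as accessions are added in random order."""

    k: np.ndarray           # subset sizes 1..n
    pan: np.ndarray         # (n_permutations, n) cumulative union sizes
    core: np.ndarray        # (n_permutations, n) cumulative intersection sizes

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "k": self.k,
            "pan_mean": self.pan.mean(axis=0),
            "pan_sd": self.pan.std(axis=0, ddof=0),
            "core_mean": self.core.mean(axis=0),
            "core_sd": self.core.std(axis=0, ddof=0),
        })


def saturation_curves(pav: PavMatrix, n_permutations: int = 100,
                      seed: int | None = None) -> SaturationCurve:
    """Pan-genome and core-genome saturation over random accession orderings.

    For each permutation the pan curve is the cumulative union of gene
    sets and the core curve the cumulative intersection, evaluated at
    every subset size k = 1..n.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    mat = pav.presence.to_numpy(dtype=bool)
    n = mat.shape[1]
    pan = np.empty((n_permutations, n), dtype=np.int64)
    core = np.empty((n_permutations, n), dtype=np.int64)
    for p in range(n_permutations):
        order = rng.permutation(n)
        cum_union = np.zeros(mat.shape[0], dtype=bool)
        cum_inter = np.ones(mat.shape[0], dtype=bool)
        for j, col in enumerate(order):
            cum_union |= mat[:, col]
            cum_inter &= mat[:, col]
            pan[p, j] = cum_union.sum()
            core[p, j] = cum_inter.sum()
    return SaturationCurve(np.arange(1, n + 1), pan, core)


def _power_law(k, A, gamma, C):
    return A * np.power(k, gamma) + C


def _exp_decay(k, A, tau, C):
    return A * np.exp(-k / tau) + C


@dataclass
class SaturationFit:
    pan_params: dict
    core_params: dict
    pan_residuals: np.ndarray | None
    core_residuals: np.ndarray | None
    converged: bool
    message: str = ""

    def pan_at(self, k):
        p = self.pan_params
        return _power_law(np.asarray(k, dtype=float), p["A"], p["gamma"], p["C"])

    def core_at(self, k):
        p = self.core_params
        return _exp_decay(np.asarray(k, dtype=float), p["A"], p["tau"], p["C"])


def fit_saturation(curve: SaturationCurve) -> SaturationFit:
    """Fit the mean pan curve with a power law A*k^gamma + C and the mean
    core curve with an exponential decay A*exp(-k/tau) + C.

    Non-convergence is reported in the result, never raised.
    """
    if len(curve.k) < 4:
        raise ValueError("need at least 4 subset sizes to fit")
    k = curve.k.astype(float)
    pan_mean = curve.pan.mean(axis=0)
    core_mean = curve.core.mean(axis=0)
    converged, msgs = True, []

    if np.ptp(pan_mean) < 1e-12:
        pan_params = {"A": 0.0, "gamma": 0.0, "C": float(pan_mean[0])}
        pan_res = np.zeros_like(pan_mean, dtype=float)
    else:
        try:
            p0 = (pan_mean[-1] - pan_mean[0], 0.5, pan_mean[0])
            popt, _ = curve_fit(_power_law, k, pan_mean, p0=p0, maxfev=20000)
            pan_params = dict(zip(("A", "gamma", "C"), map(float, popt)))
            pan_res = pan_mean - _power_law(k, *popt)
        except RuntimeError as e:  # pragma: no cover - rare
            converged, pan_params, pan_res = False, {}, None
            msgs.append(f"pan fit failed: {e}")

    if np.ptp(core_mean) < 1e-12:
        core_params = {"A": 0.0, "tau": 1.0, "C": float(core_mean[0])}
        core_res = np.zeros_like(core_mean, dtype=float)
    else:
        try:
            p0 = (core_mean[0] - core_mean[-1], max(len(k) / 3, 1.0), core_mean[-1])
            popt, _ = curve_fit(_exp_decay, k, core_mean, p0=p0, maxfev=20000)
            core_params = dict(zip(("A", "tau", "C"), map(float, popt)))
            core_res = core_mean - _exp_decay(k, *popt)
        except RuntimeError as e:  # pragma: no cover - rare
            converged, core_params, core_res = False, {}, None
            msgs.append(f"core fit failed: {e}")

    return SaturationFit(pan_params, core_params, pan_res, core_res,
                         converged, "; ".join(msgs))
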
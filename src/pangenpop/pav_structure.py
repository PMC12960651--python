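"""Population structure from the binary presence/absence matrix.

Accessions are the observations and genes the features: PCA on the
gene-centered binary matrix, Jaccard distances between presence sets,
and an average-linkage tree exported as Newick.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from skbio.tree import TreeNode

from .pav import PavMatrix


@dataclass
class Ordination:
    coordinates: pd.DataFrame            # samples x components
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame               # genes x components


def pav_pca(pav: PavMatrix, n_components: int = 5) -> Ordination:
    """PCA of accessions on the gene-centered binary matrix.

    Columns (genes) are mean-centered, no scaling (the data are binary).
    Component signs are fixed by making the largest-magnitude gene
    loading positive, so results are fully deterministic.  A constant
    matrix yields all-zero coordinates and variances.
    """
    X = pav.presence.to_numpy(dtype=float).T  # samples x genes
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA requires at least 2 samples")
    n_components = min(n_components, n - 1, p)
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: largest-|loading| gene positive per component
    for j in range(Vt.shape[0]):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    coords = U[:, :n_components] * S[:n_components]
    var = S ** 2 / max(n - 1, 1)
    total = var.sum()
    evr = var[:n_components] / total if total > 0 else np.zeros(n_components)
    cols = [f"PC{j + 1}" for j in range(n_components)]
    return Ordination(
        pd.DataFrame(coords, index=pav.presence.columns, columns=cols),
        evr,
        pd.DataFrame(Vt[:n_components].T, index=pav.presence.index, columns=cols),
    )


def jaccard_distances(pav: PavMatrix) -> pd.DataFrame:
    """Pairwise Jaccard distance 1 - |A∩B| / |A∪B| between presence sets.

    Two accessions with empty presence sets get distance 0 (with a
    warning) — they are indistinguishable on this matrix.
    """
    B = pav.presence.to_numpy(dtype=bool)
    inter = (B.T @ B.astype(np.int64)).astype(float)
    sizes = B.sum(axis=0)
    union = sizes[:, None] + sizes[None, :] - inter
    if (union == 0).any():
        warnings.warn("samples with empty presence sets; distance set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(union > 0, 1 - inter / np.maximum(union, 1), 0.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=pav.presence.columns, columns=pav.presence.columns)


@dataclass
class DistanceTree:
    distances: pd.DataFrame
    tree: TreeNode
    newick: str


def pav_distance_tree(pav: PavMatrix, method: str = "average") -> DistanceTree:
    """Agglomerative tree on Jaccard distances, exported as Newick.

    Average linkage (UPGMA-style) by default; any scipy linkage method
    is accepted.
    """
    if pav.n_samples < 3:
        raise ValueError("tree construction requires at least 3 samples")
    dist = jaccard_distances(pav)
    Z = linkage(squareform(dist.to_numpy(), checks=False), method=method)
    tree = TreeNode.from_linkage_matrix(Z, list(dist.index))
    newick = str(tree).strip()
    return DistanceTree(dist, tree, newick)


def write_newick(tree: DistanceTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.newick + "\n")
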
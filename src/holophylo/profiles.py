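"""Comparative statistics on binary presence/absence profiles.

The workflow behind gene-repertoire comparison figures: pairwise
species distances from 0/1 ortholog profiles, principal coordinate
analysis (classical metric scaling) of the distance matrix, Ward
hierarchical clustering of species (on 1 - Pearson correlation) or of
orthologs (on Euclidean distances between binary columns), and
dendrogram-driven reordering of the matrix for heatmap rendering.

The default species metric is ``pearson_complement`` (1 - phi
coefficient, range [0, 2], left unclamped) because the clustering step
operates on interspecific Pearson correlations; Jaccard and
simple-matching are available alternatives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .formats import TraitMatrix

__all__ = [
    "DistanceMatrix",
    "Ordination",
    "profile_distance",
    "pcoa",
    "ward_cluster",
    "WardResult",
    "heatmap_order",
]


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray
    metric_name: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite distances")
        if np.abs(self.values - self.values.T).max() > 1e-12:
            raise ValueError("distance matrix is not symmetric")
        np.fill_diagonal(self.values, 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class Ordination:
    labels: list[str]
    coordinates: np.ndarray  # (n, n_axes), scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray  # retained positive eigenvalues, non-increasing
    proportion_explained: np.ndarray
    negative_eigenvalue_mass: float  # |sum of dropped negatives| / sum|all|

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PCo{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.labels, columns=cols)


def _phi_coefficient(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of two 0/1 vectors via the 2x2 contingency."""
    n11 = float(np.sum((x == 1) & (y == 1)))
    n10 = float(np.sum((x == 1) & (y == 0)))
    n01 = float(np.sum((x == 0) & (y == 1)))
    n00 = float(np.sum((x == 0) & (y == 0)))
    denom = (n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00)
    if denom == 0.0:
        return np.nan
    return (n11 * n00 - n10 * n01) / np.sqrt(denom)


def profile_distance(
    matrix: TraitMatrix, metric: str = "pearson_complement"
) -> DistanceMatrix:
    """Pairwise species distances between binary profiles.

    Metrics: ``jaccard`` (1 - shared/union over sites where either is
    present), ``simple_matching`` (fraction of disagreeing sites), and
    ``pearson_complement`` (1 - phi; constant all-0/all-1 profiles have
    undefined phi and get distance 0 to identical profiles, 1 to any
    other, with a warning).
    """
    x = matrix.data.to_numpy(dtype=float)
    labels = matrix.species
    if len(labels) < 2:
        raise ValueError("need at least 2 species")
    if metric == "jaccard":
        d = squareform(pdist(x, metric="jaccard"))
    elif metric == "simple_matching":
        d = squareform(pdist(x, metric="hamming"))
    elif metric == "pearson_complement":
        n = len(labels)
        d = np.zeros((n, n))
        constant = (x.min(axis=1) == x.max(axis=1))
        if constant.any():
            warnings.warn(
                "constant profile(s) have undefined correlation; their "
                "distance is 0 to identical profiles and 1 otherwise",
                stacklevel=2,
            )
        for i in range(n):
            for j in range(i + 1, n):
                phi = _phi_coefficient(x[i], x[j])
                if np.isnan(phi):
                    dist = 0.0 if np.array_equal(x[i], x[j]) else 1.0
                else:
                    dist = 1.0 - phi
                d[i, j] = d[j, i] = dist
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(labels, d, metric)


def pcoa(dist: DistanceMatrix, n_axes: int = 2) -> Ordination:
    """Classical metric scaling (PCoA) of a distance matrix.

    Double-centers -D^2/2, eigendecomposes, keeps the positive
    eigenvalues (up to ``n_axes``); coordinates are eigenvectors scaled
    by the square root of their eigenvalue, with the sign convention
    that each axis' first non-zero loading is positive.  Negative
    eigenvalues are dropped; their relative mass is reported.
    """
    if n_axes < 1:
        raise ValueError("n_axes must be >= 1")
    d = dist.values
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(1e-12, 1e-10 * max(abs(eigval[0]), 1.0))
    positive = eigval > tol
    if not positive.any():
        raise ValueError("degenerate distances: no positive eigenvalues")
    neg_mass = float(np.abs(eigval[eigval < 0]).sum() / np.abs(eigval).sum())
    keep = np.flatnonzero(positive)[:n_axes]
    vals = eigval[keep]
    coords = eigvec[:, keep] * np.sqrt(vals)
    for a in range(coords.shape[1]):
        col = coords[:, a]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            coords[:, a] = -col
    return Ordination(
        labels=list(dist.labels),
        coordinates=coords,
        eigenvalues=vals,
        proportion_explained=vals / eigval[positive].sum(),
        negative_eigenvalue_mass=neg_mass,
    )


@dataclass
class WardResult:
    labels: list[str]  # sorted label order fed to the linkage
    linkage: np.ndarray  # scipy linkage matrix

    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def flat_clusters(self, k: int) -> pd.Series:
        assign = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(assign, index=self.labels)

    def to_newick(self) -> str:
        root = hierarchy.to_tree(self.linkage)

        def rec(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = rec(node.get_left()), rec(node.get_right())
            return f"({left},{right})"

        return rec(root) + ";"


def ward_cluster(matrix: TraitMatrix, mode: str = "species_pearson") -> WardResult:
    """Ward (variance-minimizing, Ward.D2) hierarchical clustering.

    ``species_pearson``: cluster species on 1 - Pearson correlation of
    their binary profiles.  ``orthologs_euclidean``: cluster traits on
    Euclidean distances between their presence columns.  Items are fed
    to the linkage in ascending label order so ties resolve
    deterministically.
    """
    if mode == "species_pearson":
        labels = sorted(matrix.species)
        x = matrix.data.loc[labels].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(x)
        corr = np.nan_to_num(corr, nan=0.0)
        np.fill_diagonal(corr, 1.0)
        d = 1.0 - corr  # Ward.D2: the linkage squares these inside the update
        np.fill_diagonal(d, 0.0)
        z = hierarchy.linkage(squareform(d, checks=False), method="ward")
    elif mode == "orthologs_euclidean":
        labels = sorted(matrix.traits)
        x = matrix.data[labels].to_numpy(dtype=float).T
        if not np.isfinite(x).all():
            raise ValueError("non-finite values in trait matrix")
        z = hierarchy.linkage(x, method="ward", metric="euclidean")
    else:
        raise ValueError(f"unknown clustering mode {mode!r}")
    return WardResult(labels=labels, linkage=z)


def heatmap_order(
    matrix: TraitMatrix,
    row_cluster: WardResult | None = None,
    col_cluster: WardResult | None = None,
) -> pd.DataFrame:
    """Reorder the matrix by dendrogram leaf order; values untouched."""
    df = matrix.data
    if row_cluster is not None:
        order = row_cluster.leaf_order()
        if set(order) != set(df.index):
            raise ValueError("row dendrogram labels do not match matrix species")
        df = df.loc[order]
    if col_cluster is not None:
        order = col_cluster.leaf_order()
        if set(order) != set(df.columns):
            raise ValueError("column dendrogram labels do not match matrix traits")
        df = df[order]
    return df.copy()
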
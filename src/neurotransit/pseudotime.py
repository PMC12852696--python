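"""Score-rank pseudotime and gene/cell clustering along the maturation axis.

Pseudotime is the rank of (neuron score - progenitor score) rescaled to
[0, 1]: transparent, deterministic, and monotone in the underlying
statistic.  Gene programs are obtained by Ward hierarchical clustering of
bin-averaged z-profiles; cells are clustered by PAM (k-medoids) on their
per-gene-cluster expression profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist, squareform

__all__ = ["pseudotime_order", "cluster_genes_pseudotime", "pam", "PseudotimeResult"]


def pseudotime_order(scores: pd.DataFrame) -> pd.Series:
    """Rank of (score_N - score_P) rescaled to [0, 1] (average ranks for ties)."""
    stat = scores["score_N"] - scores["score_P"]
    r = stat.rank(method="average").to_numpy()
    if len(r) == 1:
        pt = np.zeros(1)
    else:
        pt = (r - r.min()) / (r.max() - r.min()) if r.max() > r.min() else np.zeros(len(r))
    return pd.Series(pt, index=scores.index, name="pseudotime")


def pam(D: np.ndarray, k: int, max_iter: int = 100, return_medoids: bool = False):
    """Partitioning around medoids on a precomputed distance matrix.

    Deterministic: BUILD initialization followed by greedy SWAP until no
    single medoid/non-medoid exchange lowers the total within-cluster cost.
    Returns integer labels in {0..k-1}.
    """
    n = D.shape[0]
    if not (1 <= k <= n):
        raise ValueError("k must be in [1, n]")
    # BUILD: first medoid minimizes total distance, then greedy gain
    medoids = [int(np.argmin(D.sum(axis=1)))]
    dist_near = D[medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(dist_near[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        j = int(np.argmax(gains))
        medoids.append(j)
        dist_near = np.minimum(dist_near, D[j])
    medoids = list(dict.fromkeys(medoids))
    # SWAP
    for _ in range(max_iter):
        med = np.asarray(medoids)
        current = D[med].min(axis=0).sum()
        best = (0.0, None, None)
        for mi, m in enumerate(medoids):
            others = [x for x in medoids if x != m]
            if others:
                d_rest = D[others].min(axis=0)
            else:
                d_rest = np.full(n, np.inf)
            # cost after replacing m by each candidate h: sum(min(d_rest, D[h]))
            cand = np.minimum(d_rest[None, :], D).sum(axis=1)
            cand[med] = np.inf
            h = int(np.argmin(cand))
            delta = cand[h] - current
            if delta < best[0] - 1e-12:
                best = (delta, mi, h)
        if best[1] is None:
            break
        medoids[best[1]] = best[2]
    med = np.asarray(sorted(medoids))
    labels = np.argmin(D[med], axis=0)
    return (labels, med) if return_medoids else labels


@dataclass
class PseudotimeResult:
    pseudotime: pd.Series                 # per cell, in [0, 1]
    gene_clusters: pd.Series              # per gene, 1..k_genes
    cell_clusters: pd.Series              # per cell, 1..k_cells
    profiles: pd.DataFrame                # genes x pseudotime bins, z-scored
    bin_edges: np.ndarray

    def cluster_of(self, gene: str) -> int | None:
        return int(self.gene_clusters[gene]) if gene in self.gene_clusters.index else None


def _bin_means(X: np.ndarray, pt: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Equal-occupancy pseudotime bin means of a genes x cells matrix."""
    order = np.argsort(np.argsort(pt, kind="mergesort"))
    bins = np.minimum((order * n_bins) // len(pt), n_bins - 1)
    means = np.column_stack([X[:, bins == b].mean(axis=1) for b in range(n_bins)])
    edges = np.array([pt[bins == b].min() for b in range(n_bins)] + [pt.max()])
    return means, edges


def cluster_genes_pseudotime(
    norm: pd.DataFrame,
    pseudotime: pd.Series,
    k_genes: int = 6,
    k_cells: int = 4,
    n_bins: int = 20,
    genes: list[str] | None = None,
) -> PseudotimeResult:
    """Ward clustering of smoothed gene z-profiles; PAM clustering of cells.

    Each gene's normalized expression is averaged in ``n_bins``
    equal-occupancy pseudotime bins and z-scored across bins; the resulting
    profiles are clustered hierarchically (Ward, Euclidean) and cut at
    ``k_genes``.  Cells are represented by their mean expression of each
    gene cluster (z-scored per cluster) and partitioned by PAM at
    ``k_cells``.  ``genes`` restricts clustering to a pre-filtered set
    (e.g. from the pseudotime variation test).
    """
    sub = norm.loc[genes] if genes is not None else norm
    if k_genes > sub.shape[0]:
        raise ValueError("k_genes exceeds the number of genes")
    if k_cells > sub.shape[1]:
        raise ValueError("k_cells exceeds the number of cells")
    pt = pd.Series(pseudotime).reindex(sub.columns).to_numpy(dtype=float)
    X = sub.to_numpy(dtype=float)
    means, edges = _bin_means(X, pt, n_bins)
    mu = means.mean(axis=1, keepdims=True)
    sd = means.std(axis=1, keepdims=True)
    Z = np.where(sd > 0, (means - mu) / np.where(sd > 0, sd, 1.0), 0.0)

    link = sch.linkage(Z, method="ward", metric="euclidean")
    gene_labels = sch.fcluster(link, t=k_genes, criterion="maxclust")

    # per-cell profile: mean z-scored expression of each gene cluster
    cellZ = (X - X.mean(axis=1, keepdims=True)) / np.where(
        X.std(axis=1, keepdims=True) > 0, X.std(axis=1, keepdims=True), 1.0
    )
    prof = np.vstack(
        [cellZ[gene_labels == c].mean(axis=0) for c in range(1, k_genes + 1) if np.any(gene_labels == c)]
    ).T  # cells x clusters
    D = squareform(pdist(prof, metric="euclidean"))
    cell_labels = pam(D, k_cells) + 1

    return PseudotimeResult(
        pseudotime=pd.Series(pt, index=sub.columns, name="pseudotime"),
        gene_clusters=pd.Series(gene_labels, index=sub.index, name="gene_cluster"),
        cell_clusters=pd.Series(cell_labels, index=sub.columns, name="cell_cluster"),
        profiles=pd.DataFrame(Z, index=sub.index),
        bin_edges=edges,
    )
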
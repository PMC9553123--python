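"""PCA, kNN graph with adaptive-bandwidth connectivities, Leiden clustering,
and neighbor smoothing.

Genes are standardized (zero mean, unit variance, clipped at ±``clip`` SD)
before PCA; neighbors are Euclidean in PC space.  Connectivities use a
Gaussian kernel with per-cell adaptive bandwidth (the distance to the k-th
neighbor), symmetrized by the elementwise maximum, giving weights in (0, 1].
Community detection is Leiden on the weighted connectivity graph, which
guarantees internally connected communities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

__all__ = ["GraphState", "build_graph", "cluster_graph", "smooth_expression"]


@dataclass
class GraphState:
    cell_ids: np.ndarray
    pcs: np.ndarray                       # (n_cells, n_pcs)
    knn_index: np.ndarray                 # (n_cells, k), self excluded
    knn_dist: np.ndarray                  # (n_cells, k)
    connectivities: sp.csr_matrix         # symmetric, entries in (0, 1]
    genes_used: list[str]
    params: dict = field(default_factory=dict)
    labels: dict[float, np.ndarray] = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def k(self) -> int:
        return self.knn_index.shape[1]


def build_graph(
    norm: pd.DataFrame,
    genes: list[str] | pd.Index | None = None,
    n_pcs: int = 30,
    k: int = 15,
    seed: int = 0,
    clip: float = 10.0,
) -> GraphState:
    """Standardize, project to principal components and build the kNN graph."""
    genes = list(norm.columns if genes is None else genes)
    if len(genes) < n_pcs:
        raise ValueError("gene subset smaller than requested number of PCs")
    x = norm[genes].to_numpy(dtype=float)
    n_cells = x.shape[0]
    if n_pcs >= min(n_cells, len(genes)):
        raise ValueError("n_pcs must be < min(n_cells, n_genes)")
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    # relative threshold: float summation can leave sd ~1e-16 on a column
    # of identical values, which would blow up into O(1) noise
    sd[sd <= 1e-10 * np.maximum(1.0, np.abs(mu))] = 1.0
    z = np.clip((x - mu) / sd, -clip, clip)
    if np.allclose(z, 0.0):  # all cells identical: PC space is degenerate
        pcs = np.zeros((n_cells, n_pcs))
    else:
        pca = PCA(n_components=n_pcs, svd_solver="arpack", random_state=seed)
        pcs = pca.fit_transform(z)
    nn = NearestNeighbors(n_neighbors=k + 1, metric="euclidean").fit(pcs)
    dist, idx = nn.kneighbors(pcs)
    # drop self (first column once ties are resolved towards self)
    self_col = idx == np.arange(n_cells)[:, None]
    keep_idx = np.empty((n_cells, k), dtype=int)
    keep_dist = np.empty((n_cells, k))
    for i in range(n_cells):
        mask = ~self_col[i]
        if mask.sum() == k + 1:     # self not in list (duplicate points)
            mask[-1] = False
        keep_idx[i] = idx[i][mask][:k]
        keep_dist[i] = dist[i][mask][:k]
    bw = np.maximum(keep_dist[:, -1], 1e-12)
    rows = np.repeat(np.arange(n_cells), k)
    cols = keep_idx.ravel()
    d = keep_dist.ravel()
    w = np.exp(-(d**2) / (bw[rows] * bw[cols]))
    conn = sp.csr_matrix((w, (rows, cols)), shape=(n_cells, n_cells))
    conn = conn.maximum(conn.T)
    return GraphState(
        cell_ids=np.asarray(norm.index.to_numpy(dtype=object)),
        pcs=pcs,
        knn_index=keep_idx,
        knn_dist=keep_dist,
        connectivities=conn,
        genes_used=genes,
        params={"n_pcs": n_pcs, "k": k, "seed": seed, "clip": clip},
    )


def cluster_graph(g: GraphState, resolution: float, seed: int = 0) -> np.ndarray:
    """Leiden community detection on the connectivity graph.

    Maximizes RB-configuration modularity at the given resolution; communities
    are guaranteed internally connected.  Labels are relabeled to 0..K-1 by
    first occurrence so the partition is invariant to vertex order quirks.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    coo = sp.triu(g.connectivities, k=1).tocoo()
    graph = igraph.Graph(
        n=g.n_cells, edges=list(zip(coo.row.tolist(), coo.col.tolist()))
    )
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights=coo.data.tolist(),
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    raw = np.asarray(part.membership)
    _, labels = np.unique(raw, return_inverse=True)
    # stable relabel by first occurrence
    first = {}
    out = np.empty_like(labels)
    nxt = 0
    for i, lab in enumerate(labels):
        if lab not in first:
            first[lab] = nxt
            nxt += 1
        out[i] = first[lab]
    g.labels[resolution] = out
    return out


def smooth_expression(norm: pd.DataFrame, g: GraphState, gene: str) -> pd.Series:
    """Connectivity-weighted average of a gene over each cell and its neighbors.

    The cell itself enters with weight 1, so constant genes are unchanged and
    isolated spikes are attenuated but stay within the input range.
    """
    if gene not in norm.columns:
        raise KeyError(f"unknown gene {gene!r}")
    x = norm[gene].to_numpy(dtype=float)
    w = g.connectivities
    num = x + w @ x
    den = 1.0 + np.asarray(w.sum(axis=1)).ravel()
    return pd.Series(num / den, index=norm.index, name=gene)
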
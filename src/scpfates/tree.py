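"""Fate-simplex embedding, SimplePPT principal tree, root and pseudotime.

The embedding places each cell inside an equilateral unit triangle by its
three terminal-fate probabilities (barycentric coordinates; vertex order is
lexicographic in fate names) with the differentiation potential as a scaled
third axis.  SimplePPT alternates three exact minimization steps on the
regularized objective

    O(F, R, E) = sum_ij R_ij ||x_i - f_j||^2 + sigma * sum_ij R_ij log R_ij
                 + lambda * sum_{(a,b) in E} ||f_a - f_b||^2

(1) soft assignments R_ij  prop. exp(-||x_i - f_j||^2 / sigma), (2) tree
topology E = minimum spanning tree over node-node distances, (3) node
positions F from the ridge-regularized least-squares system.  Each step can
only lower O, so the objective is non-increasing (asserted).  The root is
the node maximizing the R-weighted mean root-cell probability, node
pseudotime is geodesic distance from the root along the tree, and cell
pseudotime is the R-weighted average of node pseudotimes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
from scipy.spatial.distance import cdist
from sklearn.cluster import kmeans_plusplus

__all__ = [
    "TreeConfig",
    "PrincipalTree",
    "simplex_embedding",
    "fit_simpleppt",
    "select_root",
    "compute_pseudotime",
    "segment_branches",
]


@dataclass(frozen=True)
class TreeConfig:
    n_nodes: int = 300
    sigma: float | None = None      # None: (0.15 * RMS centroid distance)^2
    lam: float = 10.0
    max_iter: int = 200
    tol: float = 1.0e-4             # max node movement
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 3:
            raise ValueError("need at least 3 nodes")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.lam <= 0:
            raise ValueError("lambda must be positive")


@dataclass
class PrincipalTree:
    X: np.ndarray                   # cell coordinates (n, d)
    F: np.ndarray                   # node positions (n_nodes, d)
    edges: np.ndarray               # (n_nodes - 1, 2)
    R: np.ndarray                   # soft assignments (n, n_nodes)
    sigma: float
    lam: float
    converged: bool
    objective: list[float] = field(default_factory=list)
    root: int | None = None
    node_pseudotime: np.ndarray | None = None
    cell_pseudotime: np.ndarray | None = None
    cell_segment: np.ndarray | None = None
    segments: pd.DataFrame | None = None
    bifurcations: pd.DataFrame | None = None

    @property
    def n_nodes(self) -> int:
        return self.F.shape[0]

    def adjacency(self) -> sp.csr_matrix:
        d = np.linalg.norm(self.F[self.edges[:, 0]] - self.F[self.edges[:, 1]], axis=1)
        n = self.n_nodes
        a = sp.csr_matrix(
            (np.concatenate([d, d]),
             (np.concatenate([self.edges[:, 0], self.edges[:, 1]]),
              np.concatenate([self.edges[:, 1], self.edges[:, 0]]))),
            shape=(n, n),
        )
        return a

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg


def simplex_embedding(
    absorption: pd.DataFrame, dp: np.ndarray, scale: float = 1.0
) -> np.ndarray:
    """Barycentric fate-triangle coordinates plus a scaled potential axis.

    ``absorption`` must have exactly three columns summing to one per row;
    vertices are assigned in lexicographic fate-name order on an equilateral
    triangle of unit side.  Output shape is (n, 3).
    """
    if absorption.shape[1] != 3:
        raise ValueError(
            "simplex embedding expects exactly 3 terminal states "
            f"(got {absorption.shape[1]})"
        )
    cols = sorted(absorption.columns)
    a = absorption[cols].to_numpy(dtype=float)
    if not np.allclose(a.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("absorption rows must sum to 1")
    verts = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3.0) / 2.0]])
    xy = a @ verts
    dp = np.asarray(dp, dtype=float).ravel()
    return np.column_stack([xy, scale * dp])


def _mst_edges(f: np.ndarray) -> np.ndarray:
    d2 = cdist(f, f) ** 2
    # constant offset keeps the MST unchanged but prevents scipy from
    # dropping zero-weight edges between coincident nodes (a dropped edge
    # would silently turn the tree into a forest)
    mst = csgraph.minimum_spanning_tree(d2 + 1.0)
    coo = mst.tocoo()
    edges = np.column_stack([coo.row, coo.col]).astype(int)
    assert len(edges) == f.shape[0] - 1, "MST is not spanning"
    return edges


def fit_simpleppt(x: np.ndarray, cfg: TreeConfig = TreeConfig()) -> PrincipalTree:
    """Fit a principal tree to a point cloud by the SimplePPT iteration."""
    x = np.asarray(x, dtype=float)
    n, d = x.shape
    n_nodes = cfg.n_nodes
    if n < n_nodes:
        warnings.warn(f"only {n} cells; lowering n_nodes from {n_nodes} to {n}")
        n_nodes = n
    f, _ = kmeans_plusplus(x, n_clusters=n_nodes, random_state=cfg.seed)
    if cfg.sigma is None:
        # bandwidth tied to the global spread of the embedding: narrow enough
        # to resolve branches, wide enough that nodes average over noise
        rms = float(np.sqrt(((x - x.mean(axis=0)) ** 2).sum(axis=1).mean()))
        sigma = (0.15 * rms) ** 2 if rms > 0 else 1.0
    else:
        sigma = cfg.sigma

    edges = _mst_edges(f)
    objective: list[float] = []
    converged = False
    r = None
    for _ in range(cfg.max_iter):
        d2 = cdist(x, f) ** 2
        logits = -d2 / sigma
        logits -= logits.max(axis=1, keepdims=True)
        r = np.exp(logits)
        r /= r.sum(axis=1, keepdims=True)

        edges = _mst_edges(f)

        # node update: (diag(R^T 1) + lambda L) F = R^T X, L the tree Laplacian
        w = r.sum(axis=0)
        lap = sp.csgraph.laplacian(
            sp.csr_matrix(
                (np.ones(2 * len(edges)),
                 (np.concatenate([edges[:, 0], edges[:, 1]]),
                  np.concatenate([edges[:, 1], edges[:, 0]]))),
                shape=(n_nodes, n_nodes),
            )
        )
        lhs = sp.diags(w) + cfg.lam * lap
        f_new = sp.linalg.spsolve(sp.csc_matrix(lhs), r.T @ x)
        f_new = np.asarray(f_new).reshape(n_nodes, d)

        move = float(np.max(np.linalg.norm(f_new - f, axis=1)))
        f = f_new

        d2 = cdist(x, f) ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = np.where(r > 0, r * np.log(r), 0.0).sum()
        edge_len2 = ((f[edges[:, 0]] - f[edges[:, 1]]) ** 2).sum()
        obj = float((r * d2).sum() + sigma * ent + cfg.lam * edge_len2)
        if objective and obj > objective[-1] + 1e-6 * (1 + abs(objective[-1])):
            raise AssertionError(
                f"SimplePPT objective increased: {objective[-1]} -> {obj}"
            )
        objective.append(obj)
        if move < cfg.tol:
            converged = True
            break
    edges = _mst_edges(f)
    d2 = cdist(x, f) ** 2
    logits = -d2 / sigma
    logits -= logits.max(axis=1, keepdims=True)
    r = np.exp(logits)
    r /= r.sum(axis=1, keepdims=True)
    return PrincipalTree(
        X=x, F=f, edges=edges, R=r, sigma=sigma, lam=cfg.lam,
        converged=converged, objective=objective,
    )


def select_root(
    tree: PrincipalTree, root_prob: np.ndarray, leaves_only: bool = False
) -> int:
    """Node with the highest soft-assignment-weighted mean root probability.

    With ``leaves_only`` the choice is restricted to degree-1 nodes: the
    origin of a differentiation trajectory is an endpoint of the principal
    tree, and tiny interior nodes (a handful of cells each) are easily won
    by single noisy cells.
    """
    root_prob = np.asarray(root_prob, dtype=float).ravel()
    if root_prob.shape[0] != tree.R.shape[0]:
        raise ValueError("root_prob must align with cells")
    if np.all(root_prob == 0):
        raise ValueError("all-zero root probabilities")
    w = tree.R.sum(axis=0)
    score = (tree.R * root_prob[:, None]).sum(axis=0) / np.maximum(w, 1e-300)
    if leaves_only:
        allowed = np.flatnonzero(tree.degrees() == 1)
    else:
        allowed = np.arange(tree.n_nodes)
    best = float(score[allowed].max())
    tree.root = int(allowed[np.flatnonzero(score[allowed] == best)[0]])
    return tree.root


def compute_pseudotime(tree: PrincipalTree) -> tuple[np.ndarray, np.ndarray]:
    """Geodesic node pseudotime from the root; soft-projected cell pseudotime."""
    if tree.root is None:
        raise ValueError("select a root before computing pseudotime")
    adj = tree.adjacency()
    node_pt = csgraph.dijkstra(adj, indices=tree.root, directed=False)
    cell_pt = tree.R @ node_pt
    tree.node_pseudotime = node_pt
    tree.cell_pseudotime = cell_pt
    return node_pt, cell_pt


def segment_branches(tree: PrincipalTree) -> tuple[np.ndarray, pd.DataFrame]:
    """Decompose the tree into branches and locate bifurcations.

    Segments are maximal paths between nodes of degree != 2 (the root counts
    as a boundary even when it has degree 2).  Every cell is labeled by the
    segment of its argmax-assignment node.  The bifurcation table lists every
    node of degree >= 3 with its pseudotime.
    """
    if tree.node_pseudotime is None:
        raise ValueError("compute pseudotime before segmenting")
    deg = tree.degrees()
    boundary = (deg != 2)
    if tree.root is not None:
        boundary[tree.root] = True
    nbrs: dict[int, list[int]] = {i: [] for i in range(tree.n_nodes)}
    for a, b in tree.edges:
        nbrs[a].append(int(b))
        nbrs[b].append(int(a))
    node_seg = np.full(tree.n_nodes, -1, dtype=int)
    seg_rows = []
    seg_id = 0
    visited_edges = set()
    for start in np.flatnonzero(boundary):
        for nxt in nbrs[start]:
            if (start, nxt) in visited_edges:
                continue
            path = [start, nxt]
            visited_edges.add((start, nxt))
            visited_edges.add((nxt, start))
            while not boundary[path[-1]]:
                prev, cur = path[-2], path[-1]
                nxt2 = [m for m in nbrs[cur] if m != prev][0]
                visited_edges.add((cur, nxt2))
                visited_edges.add((nxt2, cur))
                path.append(nxt2)
            inner = path if node_seg[path[0]] == -1 else path[1:]
            for m in inner:
                if node_seg[m] == -1 or not boundary[m]:
                    node_seg[m] = seg_id
            pt = tree.node_pseudotime
            seg_rows.append(
                {
                    "segment": seg_id,
                    "start_node": path[0],
                    "end_node": path[-1],
                    "n_nodes": len(path),
                    "pt_start": float(min(pt[path[0]], pt[path[-1]])),
                    "pt_end": float(max(pt[path[0]], pt[path[-1]])),
                }
            )
            seg_id += 1
    if seg_id == 0:  # single node or linear degenerate
        node_seg[:] = 0
        seg_rows.append(
            {"segment": 0, "start_node": tree.root or 0,
             "end_node": tree.root or 0, "n_nodes": tree.n_nodes,
             "pt_start": 0.0, "pt_end": float(tree.node_pseudotime.max())}
        )
    segments = pd.DataFrame(seg_rows).set_index("segment")
    argmax_node = tree.R.argmax(axis=1)
    cell_segment = node_seg[argmax_node]
    bif_nodes = np.flatnonzero(deg >= 3)
    bifurcations = pd.DataFrame(
        {
            "node": bif_nodes,
            "degree": deg[bif_nodes],
            "pseudotime": tree.node_pseudotime[bif_nodes],
        }
    ).sort_values("pseudotime").reset_index(drop=True)
    tree.cell_segment = cell_segment
    tree.segments = segments
    tree.bifurcations = bifurcations
    return cell_segment, bifurcations
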
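"""Steady-state RNA velocity from spliced/unspliced layers.

Genes are retained when their shared spliced/unspliced count reaches 20, and
the top 4000 by the overdispersion statistic of the spliced counts are kept.
First-order moments Ms, Mu are kNN averages of the size-normalized layers on
a graph built from 30 PCs of the spliced matrix (k=15).  Per gene the
degradation ratio gamma is the zero-intercept least-squares slope of Mu on Ms
over the extreme quantiles of Ms+Mu (the steady-state model), velocity is
V = Mu - gamma * Ms, and transitions follow an exponential kernel on the
cosine similarity between a cell's velocity and the displacement towards each
of its graph neighbors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .container import CountContainer
from .graph import GraphState, build_graph
from .qc import find_overdispersed

__all__ = [
    "VelocityModel",
    "select_velocity_genes",
    "compute_moments",
    "fit_steady_state_velocity",
    "build_velocity_transition",
    "run_velocity",
]


@dataclass
class VelocityModel:
    genes: list[str]
    Ms: np.ndarray
    Mu: np.ndarray
    gamma: pd.Series
    V: np.ndarray
    scores: sp.csr_matrix | None = None
    transition: sp.csr_matrix | None = None
    graph: GraphState | None = None
    params: dict = field(default_factory=dict)


def _require_layers(c: CountContainer) -> None:
    for layer in ("spliced", "unspliced"):
        if layer not in c.layers:
            raise ValueError(
                f"container lacks the {layer!r} layer; velocity needs "
                "spliced/unspliced input (e.g. from a velocyto-style counter)"
            )


def _size_normalize(mat: sp.csr_matrix) -> np.ndarray:
    x = np.asarray(mat.todense(), dtype=float)
    lib = x.sum(axis=1)
    target = np.median(lib[lib > 0])
    lib[lib == 0] = 1.0
    return x * (target / lib)[:, None]


def select_velocity_genes(
    c: CountContainer,
    min_shared_counts: int = 20,
    n_top_genes: int = 4000,
) -> list[str]:
    """Shared-count filter then top genes by spliced-count overdispersion.

    The shared count of a gene is the total of min(spliced, unspliced) over
    cells, so a gene must be seen in both layers of the same cell to count.
    """
    _require_layers(c)
    s = np.asarray(c.layer("spliced").todense())
    u = np.asarray(c.layer("unspliced").todense())
    keep = ~c.ercc
    shared = np.minimum(s, u).sum(axis=0)
    ok = keep & (shared >= min_shared_counts)
    genes = c.gene_ids[ok]
    if genes.size == 0:
        raise ValueError("no genes pass the shared-count filter")
    sn = _size_normalize(c.layer("spliced")[:, ok])
    norm = pd.DataFrame(np.log1p(sn), index=c.cell_ids, columns=genes)
    _, disp = find_overdispersed(norm)
    ranked = disp["z"].sort_values(ascending=False).index
    return list(ranked[: min(n_top_genes, len(ranked))])


def compute_moments(
    c: CountContainer,
    g: GraphState | None = None,
    genes: list[str] | None = None,
    n_pcs: int = 30,
    k: int = 15,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, GraphState, list[str]]:
    """kNN-smoothed first moments of the normalized spliced/unspliced layers.

    Ms_i (Mu_i) is the unweighted mean over cell i and its k neighbors in the
    graph built on the PCs of the spliced matrix.  With k=0 the moments equal
    the normalized input.
    """
    _require_layers(c)
    if genes is None:
        genes = select_velocity_genes(c)
    pos = pd.Index(c.gene_ids).get_indexer(genes)
    s = _size_normalize(c.layer("spliced")[:, pos])
    u = _size_normalize(c.layer("unspliced")[:, pos])
    if g is None:
        norm = pd.DataFrame(np.log1p(s), index=c.cell_ids, columns=genes)
        if k == 0:
            return s, u, None, genes  # degenerate config: raw normalized input
        g = build_graph(norm, n_pcs=min(n_pcs, len(genes) - 1, s.shape[0] - 1),
                        k=k, seed=seed)
    n = s.shape[0]
    rows = np.repeat(np.arange(n), g.k + 1)
    cols = np.hstack([np.arange(n)[:, None], g.knn_index]).ravel()
    w = sp.csr_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))
    w = w.multiply(1.0 / w.sum(axis=1))
    Ms = np.asarray(w @ s)
    Mu = np.asarray(w @ u)
    return Ms, Mu, g, genes


def fit_steady_state_velocity(
    Ms: np.ndarray,
    Mu: np.ndarray,
    genes: list[str] | None = None,
    quantile: float = 0.05,
) -> tuple[pd.Series, np.ndarray, list[str]]:
    """Per-gene degradation ratio and velocity under the steady-state model.

    gamma is the zero-intercept LS slope of Mu on Ms over the union of the
    bottom and top ``quantile`` of Ms+Mu; V = Mu - gamma*Ms.  Genes with fewer
    than 4 extreme cells are dropped with a warning.
    """
    n, m = Ms.shape
    if genes is None:
        genes = [f"gene{i}" for i in range(m)]
    n_ext = max(int(np.ceil(quantile * n)), 2)
    total = Ms + Mu
    order = np.argsort(total, axis=0)
    ext = np.concatenate([order[:n_ext], order[-n_ext:]], axis=0)
    cols = np.broadcast_to(np.arange(m), ext.shape)
    ms_e = Ms[ext, cols]
    mu_e = Mu[ext, cols]
    denom = (ms_e**2).sum(axis=0)
    valid = (denom > 0) & (ext.shape[0] >= 4)
    if not valid.all():
        warnings.warn(
            f"{(~valid).sum()} genes dropped: gamma undefined "
            "(no expression among extreme cells)"
        )
    gamma = np.zeros(m)
    gamma[valid] = (ms_e * mu_e).sum(axis=0)[valid] / denom[valid]
    gamma = np.maximum(gamma, 0.0)
    kept = [g for g, v in zip(genes, valid) if v]
    idx = np.where(valid)[0]
    V = Mu[:, idx] - gamma[idx][None, :] * Ms[:, idx]
    return pd.Series(gamma[idx], index=kept, name="gamma"), V, kept


def build_velocity_transition(
    V: np.ndarray,
    Ms: np.ndarray,
    g: GraphState,
    kernel_scale: float = 0.1,
) -> tuple[sp.csr_matrix, sp.csr_matrix]:
    """Cosine velocity-graph scores and the row-stochastic transition matrix.

    score_ij = cos(V_i, Ms_j - Ms_i) for j among i's graph neighbors;
    T_i = softmax(score_i / kernel_scale).  A cell with zero velocity (or all
    zero displacements) gets a uniform row over its neighbors.
    """
    n, k = g.knn_index.shape
    scores = np.zeros((n, k))
    probs = np.empty((n, k))
    vnorm = np.linalg.norm(V, axis=1)
    for i in range(n):
        nbr = g.knn_index[i]
        disp = Ms[nbr] - Ms[i]
        dnorm = np.linalg.norm(disp, axis=1)
        ok = (dnorm > 0) & (vnorm[i] > 0)
        s_i = np.zeros(k)
        s_i[ok] = (disp[ok] @ V[i]) / (dnorm[ok] * vnorm[i])
        scores[i] = s_i
        if vnorm[i] == 0:
            probs[i] = 1.0 / k
        else:
            e = np.exp((s_i - s_i.max()) / kernel_scale)
            probs[i] = e / e.sum()
    rows = np.repeat(np.arange(n), k)
    cols = g.knn_index.ravel()
    score_mat = sp.csr_matrix((scores.ravel(), (rows, cols)), shape=(n, n))
    t_mat = sp.csr_matrix((probs.ravel(), (rows, cols)), shape=(n, n))
    return score_mat, t_mat


def run_velocity(
    c: CountContainer,
    min_shared_counts: int = 20,
    n_top_genes: int = 4000,
    n_pcs: int = 30,
    k: int = 15,
    quantile: float = 0.05,
    kernel_scale: float = 0.1,
    seed: int = 0,
) -> VelocityModel:
    """Full velocity stage: gene selection, moments, gamma fit, transitions."""
    genes = select_velocity_genes(c, min_shared_counts, n_top_genes)
    Ms, Mu, g, genes = compute_moments(c, genes=genes, n_pcs=n_pcs, k=k, seed=seed)
    gamma, V, kept = fit_steady_state_velocity(Ms, Mu, genes, quantile)
    pos = pd.Index(genes).get_indexer(kept)
    scores, T = build_velocity_transition(V, Ms[:, pos], g, kernel_scale)
    return VelocityModel(
        genes=kept, Ms=Ms[:, pos], Mu=Mu[:, pos], gamma=gamma, V=V,
        scores=scores, transition=T, graph=g,
        params={
            "min_shared_counts": min_shared_counts, "n_top_genes": n_top_genes,
            "n_pcs": n_pcs, "k": k, "quantile": quantile,
            "kernel_scale": kernel_scale, "seed": seed,
        },
    )
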
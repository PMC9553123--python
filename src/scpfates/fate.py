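"""Fate analysis on the cell-cell transition matrix.

The velocity kernel is blended with a connectivity kernel (30% connectivity
share by default), terminal states are picked by cluster-level metastability,
fate probabilities are absorption probabilities of the resulting absorbing
Markov chain, root cells come from the stationary distribution of the
time-reversed chain, and a CytoTRACE-style differentiation potential is
derived from per-cell detected-gene counts.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .container import CountContainer, ResultTable
from .graph import GraphState

__all__ = [
    "combine_kernels",
    "select_terminal_states",
    "absorption_probabilities",
    "root_probabilities",
    "differentiation_potential",
    "tip_markers",
]


def _row_normalize(m: sp.spmatrix) -> sp.csr_matrix:
    m = sp.csr_matrix(m, dtype=float)
    rowsum = np.asarray(m.sum(axis=1)).ravel()
    rowsum[rowsum == 0] = 1.0
    return sp.diags(1.0 / rowsum) @ m


def combine_kernels(
    t_vel: sp.spmatrix, g: GraphState, w: float = 0.30
) -> sp.csr_matrix:
    """T = (1-w) * T_vel + w * T_conn, with T_conn the row-normalized
    connectivities.  ``w`` is the connectivity share."""
    if not 0.0 <= w <= 1.0:
        raise ValueError("connectivity weight w must lie in [0, 1]")
    t_vel = _row_normalize(t_vel)
    t_conn = _row_normalize(g.connectivities)
    return sp.csr_matrix((1.0 - w) * t_vel + w * t_conn)


def select_terminal_states(
    t: sp.spmatrix,
    labels: np.ndarray,
    n_macrostates: int = 6,
    n_terminal: int = 3,
    terminal_names: list[int] | None = None,
) -> dict[str, np.ndarray]:
    """Terminal cell sets from cluster-level metastability.

    A cluster's metastability is the mean within-cluster transition mass of
    its cells; the ``n_macrostates`` most metastable clusters are candidate
    macrostates.  Terminal sets are the user-named clusters if given,
    otherwise the candidates with the lowest mean outgoing flow into the
    other candidates.  Ties break towards the lower cluster id.
    """
    t = sp.csr_matrix(t, dtype=float)
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if terminal_names is not None:
        missing = [c for c in terminal_names if c not in clusters]
        if missing:
            raise ValueError(f"requested terminal clusters absent: {missing}")
        return {
            str(c): np.where(labels == c)[0] for c in terminal_names
        }
    meta = {}
    for c in clusters:
        members = labels == c
        block = t[np.where(members)[0]][:, np.where(members)[0]]
        meta[c] = float(np.asarray(block.sum(axis=1)).mean())
    # sort by metastability desc, cluster id asc on ties
    candidates = sorted(clusters, key=lambda c: (-meta[c], c))[:n_macrostates]
    # terminal candidates lose the least mass to the rest of the chain;
    # 1 - metastability is exactly that outgoing flow
    outflow = {c: 1.0 - meta[c] for c in candidates}
    chosen = sorted(candidates, key=lambda c: (outflow[c], c))[:n_terminal]
    return {str(c): np.where(labels == c)[0] for c in sorted(chosen)}


def absorption_probabilities(
    t: sp.spmatrix, terminal: dict[str, np.ndarray]
) -> pd.DataFrame:
    """Absorption probabilities of each cell into each terminal set.

    Terminal cells are made absorbing; for the transient block Q and the
    (set-aggregated) absorbing block R the transient rows solve
    (I - Q) A = R.  Every row sums to 1; a terminal cell's row is the
    indicator of its own set.  A transient cell with no path into any
    terminal set is an error naming the cell.
    """
    t = sp.csr_matrix(t, dtype=float)
    n = t.shape[0]
    names = sorted(terminal)
    term_idx = np.concatenate([np.asarray(terminal[k]) for k in names])
    if len(np.unique(term_idx)) != term_idx.size:
        raise ValueError("terminal sets must be disjoint")
    is_term = np.zeros(n, dtype=bool)
    is_term[term_idx] = True
    trans_idx = np.where(~is_term)[0]
    # reachability: a transient cell must have a forward path into some
    # terminal set; BFS on the reversed edges from every terminal cell
    rev = sp.csr_matrix((t.T > 0).astype(np.int8))
    reachable = np.zeros(n, dtype=bool)
    reachable[term_idx] = True
    for start in term_idx:
        if reachable.all():
            break
        order = csgraph.breadth_first_order(
            rev, i_start=int(start), return_predecessors=False
        )
        reachable[order] = True
    bad = trans_idx[~reachable[trans_idx]]
    if bad.size:
        raise ValueError(
            f"cell index {int(bad[0])} has no path to any terminal set"
        )
    q = t[trans_idx][:, trans_idx]
    a_t = np.empty((trans_idx.size, len(names)))
    lhs = sp.identity(trans_idx.size, format="csc") - q.tocsc()
    lu = sp.linalg.splu(lhs)
    for j, k in enumerate(names):
        r_j = np.asarray(t[trans_idx][:, np.asarray(terminal[k])].sum(axis=1)).ravel()
        a_t[:, j] = lu.solve(r_j)
    a = np.zeros((n, len(names)))
    a[trans_idx] = a_t
    for j, k in enumerate(names):
        a[np.asarray(terminal[k]), j] = 1.0
    a = np.clip(a, 0.0, 1.0)
    a /= a.sum(axis=1, keepdims=True)
    return pd.DataFrame(a, columns=names)


def root_probabilities(
    t: sp.spmatrix, eps: float = 0.01, max_iter: int = 10000
) -> np.ndarray:
    """Root-cell probabilities from the time-reversed chain.

    The backward matrix is the row-normalized transpose of T; its stationary
    distribution (found by power iteration to tolerance ``eps`` on the L1
    residual, scaled by n) concentrates where backward dynamics accumulate,
    i.e. at the roots.  The result is scaled to [0, 1] by its maximum.
    """
    b = _row_normalize(sp.csr_matrix(t).T)
    n = b.shape[0]
    pi = np.full(n, 1.0 / n)
    tol = eps / n
    residual = np.inf
    for _ in range(max_iter):
        # lazy chain (I + B)/2 shares the stationary vector and cannot
        # oscillate on periodic structure
        nxt = 0.5 * pi + 0.5 * np.asarray(pi @ b).ravel()
        nxt /= nxt.sum()
        residual = np.abs(nxt - pi).sum()
        pi = nxt
        if residual < tol:
            break
    else:
        raise RuntimeError(
            f"power iteration did not converge: residual {residual:.3g}"
        )
    if pi.max() <= 0:
        raise ValueError("degenerate stationary distribution")
    return pi / pi.max()


def differentiation_potential(
    c: CountContainer,
    g: GraphState,
    n_top: int = 200,
    n_smooth: int = 3,
    alpha: float = 0.7,
) -> pd.Series:
    """CytoTRACE-style differentiation potential from raw counts.

    The number of detected genes per cell (GC) is correlated with every
    gene's expression; the signature is the mean log-normalized expression of
    the ``n_top`` most GC-correlated genes, smoothed by ``n_smooth`` rounds of
    alpha-damped neighbor averaging, and rank-scaled to [0, 1] (progenitors
    high).
    """
    counts = np.asarray(c.layer("total").todense(), dtype=float)[:, ~c.ercc]
    if n_top > counts.shape[1]:
        raise ValueError("n_top exceeds the number of measured genes")
    gc = (counts > 0).sum(axis=1).astype(float)
    lib = counts.sum(axis=1)
    lib[lib == 0] = 1.0
    logn = np.log1p(counts * (np.median(lib) / lib)[:, None])
    xc = logn - logn.mean(axis=0)
    gcc = gc - gc.mean()
    denom = np.sqrt((xc**2).sum(axis=0) * (gcc**2).sum())
    denom[denom == 0] = np.inf
    corr = (xc * gcc[:, None]).sum(axis=0) / denom
    top = np.argsort(corr)[::-1][:n_top]
    sig = logn[:, top].mean(axis=1)
    w = _row_normalize(g.connectivities)
    for _ in range(n_smooth):
        sig = (1.0 - alpha) * sig + alpha * np.asarray(w @ sig).ravel()
    # min-rank keeps the score range exactly [0, 1] even with ties
    ranks = stats.rankdata(sig, method="min") - 1.0
    score = ranks / max(ranks.max(), 1.0)
    return pd.Series(score, index=pd.Index(c.cell_ids, name="cell_id"),
                     name="differentiation_potential")


def tip_markers(
    norm: pd.DataFrame,
    absorption: pd.DataFrame,
    terminal: dict[str, np.ndarray],
    n_tip: int = 15,
) -> ResultTable:
    """Marker t-tests for the tip cells of each terminal state.

    The tip of a fate is its ``n_tip`` member cells with the highest
    absorption probability for that fate; each gene is tested tip vs all
    other cells with a two-sample t-test, BH-corrected, and ranked by effect
    size (mean difference).  Constant genes report p = 1.
    """
    frames = []
    for fate in sorted(terminal):
        members = np.asarray(terminal[fate])
        if members.size < n_tip:
            raise ValueError(
                f"terminal set {fate!r} has {members.size} cells < n_tip={n_tip}"
            )
        probs = absorption[fate].to_numpy()[members]
        tip = members[np.argsort(probs)[::-1][:n_tip]]
        mask = np.zeros(len(norm), dtype=bool)
        mask[tip] = True
        x = norm.to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            t_stat, p = stats.ttest_ind(x[mask], x[~mask], axis=0)
        constant = x.max(axis=0) == x.min(axis=0)
        t_stat = np.where(constant, 0.0, t_stat)
        p = np.where(constant | np.isnan(p), 1.0, p)
        effect = x[mask].mean(axis=0) - x[~mask].mean(axis=0)
        _, q, _, _ = multipletests(p, method="fdr_bh")
        df = pd.DataFrame(
            {
                "fate": fate,
                "t": np.where(np.isnan(t_stat), 0.0, t_stat),
                "p": p,
                "q": q,
                "effect": effect,
            },
            index=norm.columns,
        ).sort_values("effect", ascending=False)
        df["tip_cells"] = ",".join(norm.index[mask].astype(str))
        frames.append(df.reset_index().rename(columns={"index": "gene"}))
    out = pd.concat(frames, ignore_index=True)
    out.index = pd.Index(
        [f"{r.fate}:{r.gene}" for r in out.itertuples()], name="key"
    )
    return ResultTable(table=out, stage="tip_markers", params={"n_tip": n_tip})
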
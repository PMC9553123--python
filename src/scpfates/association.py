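"""Pseudotime association, trend matrices, early markers and branching tests.

Association of a gene with the trajectory compares a penalized cubic
B-spline smooth of pseudotime (Gaussian response on log-normalized
expression) against an intercept-only model with an F-test on residual sums
of squares using effective degrees of freedom; the smoothing parameter is
chosen per gene by generalized cross-validation over a fixed grid.  BH
correction is applied across tested genes (default FDR cutoff 1e-4).

Early fate markers re-run the same test on cells restricted to pseudotime up
to the first chromaffin bifurcation — structurally, the divergence node of
the two late-splitting (chromaffin) fates — separately along the glial and
chromaffin paths.  Branching analysis keeps genes with a positive
significant linear slope over progenitor + branch cells, then tests a
smooth-by-branch interaction (exp ~ s(pt)*branch vs exp ~ s(pt)).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline
from statsmodels.stats.multitest import multipletests

from .tree import PrincipalTree

__all__ = [
    "test_association",
    "binned_trends",
    "first_chromaffin_bifurcation",
    "early_path_markers",
    "test_branch_genes",
]

_LAMBDA_GRID = tuple(float(x) for x in np.logspace(-2.0, 4.0, 13))


def _bspline_design(t: np.ndarray, n_basis: int, degree: int = 3) -> np.ndarray:
    """Clamped B-spline design matrix with ``n_basis`` columns over range(t)."""
    lo, hi = float(t.min()), float(t.max())
    if hi <= lo:
        raise ValueError("pseudotime is constant; association undefined")
    n_inner = n_basis - degree - 1
    if n_inner < 0:
        raise ValueError("n_basis too small for the spline degree")
    inner = np.linspace(lo, hi, n_inner + 2)[1:-1]
    knots = np.r_[[lo] * (degree + 1), inner, [hi] * (degree + 1)]
    return BSpline.design_matrix(t, knots, degree, extrapolate=True).toarray()


def _penalized_fits(
    b: np.ndarray, y: np.ndarray, lambdas: tuple[float, ...],
    pen: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """RSS and edf per lambda; returns (rss, edf, pooled best index).

    The second-difference penalty on spline coefficients is the standard
    P-spline roughness penalty.  One smoothing parameter is chosen for the
    whole gene family by minimizing the summed GCV n*RSS/(n-edf)^2 — a
    per-gene choice would make the F-test anti-conservative through
    selection, while the pooled choice amortizes selection over thousands of
    genes and keeps the null calibrated.
    """
    n, k = b.shape
    if pen is None:
        d2 = np.diff(np.eye(k), n=2, axis=0)
        pen = d2.T @ d2
    btb = b.T @ b
    bty = b.T @ y
    rss = np.empty((len(lambdas), y.shape[1]))
    edf = np.empty(len(lambdas))
    ridge = 1e-10 * np.eye(k)
    for i, lam in enumerate(lambdas):
        m = np.linalg.solve(btb + lam * pen + ridge, np.eye(k))
        coef = m @ bty
        fit = b @ coef
        rss[i] = ((y - fit) ** 2).sum(axis=0)
        edf[i] = float(np.trace(b @ m @ b.T))
    with np.errstate(divide="ignore", invalid="ignore"):
        gcv = (n * rss / (n - edf[:, None]) ** 2).sum(axis=1)
    best = int(np.argmin(gcv))
    return rss, edf, best


def test_association(
    norm: pd.DataFrame,
    pseudotime: np.ndarray,
    cells: np.ndarray | None = None,
    fdr_cutoff: float = 1.0e-4,
    n_basis: int = 6,
    degree: int = 3,
    lambdas: tuple[float, ...] = _LAMBDA_GRID,
    n_grid: int = 50,
) -> pd.DataFrame:
    """Per-gene pseudotime association F-test (smooth vs intercept).

    Returns a table with F, p, q (BH), significant flag, edf, the fitted
    smooth evaluated on ``n_grid`` equally spaced pseudotime points
    ("trend_*" columns) and the activation bin of the min-max normalized
    trend (first of 10 bins exceeding 0.5; -1 for flat genes).
    """
    pt = np.asarray(pseudotime, dtype=float).ravel()
    if cells is not None:
        cells = np.asarray(cells)
        norm = norm.iloc[cells] if cells.dtype != bool else norm.loc[cells]
        pt = pt[cells]
    n = len(pt)
    if n < 20:
        raise ValueError("need at least 20 cells for association testing")
    y = norm.to_numpy(dtype=float)
    y0 = y - y.mean(axis=0)
    rss0 = (y0**2).sum(axis=0)
    b = _bspline_design(pt, n_basis, degree)
    rss, edf, best = _penalized_fits(b, y, lambdas)
    rss1 = rss[best]
    edf1 = float(edf[best])
    df1 = max(edf1 - 1.0, 1e-8)
    df2 = max(n - edf1, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss0 - rss1) / df1) / (rss1 / df2)
    flat = (rss0 <= 1e-12) | ~np.isfinite(f)
    f = np.where(flat, 0.0, np.maximum(f, 0.0))
    p = np.where(flat, 1.0, stats.f.sf(f, df1, df2))
    _, q, _, _ = multipletests(p, method="fdr_bh")

    grid = np.linspace(pt.min(), pt.max(), n_grid)
    bg = _bspline_design_like(grid, pt, n_basis, degree)
    k = b.shape[1]
    d2 = np.diff(np.eye(k), n=2, axis=0)
    pen = d2.T @ d2
    coef = np.linalg.solve(b.T @ b + lambdas[best] * pen, b.T @ y)
    trends = (bg @ coef).T
    act_bin = _activation_bins(trends)
    out = pd.DataFrame(
        {
            "F": f,
            "p": p,
            "q": q,
            "significant": q < fdr_cutoff,
            "edf": edf1,
            "activation_bin": act_bin,
            "rising": trends[:, -1] > trends[:, 0],
        },
        index=norm.columns.rename("gene"),
    )
    for j in range(n_grid):
        out[f"trend_{j}"] = trends[:, j]
    out.attrs["pseudotime_grid"] = grid
    return out


def _bspline_design_like(
    grid: np.ndarray, t: np.ndarray, n_basis: int, degree: int
) -> np.ndarray:
    lo, hi = float(t.min()), float(t.max())
    n_inner = n_basis - degree - 1
    inner = np.linspace(lo, hi, n_inner + 2)[1:-1]
    knots = np.r_[[lo] * (degree + 1), inner, [hi] * (degree + 1)]
    return BSpline.design_matrix(grid, knots, degree, extrapolate=True).toarray()


def _activation_bins(trends: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """First of n_bins (over the trend grid) where the min-max normalized
    trend exceeds 0.5; -1 for flat trends."""
    lo = trends.min(axis=1, keepdims=True)
    hi = trends.max(axis=1, keepdims=True)
    span = hi - lo
    flat = span.ravel() <= 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (trends - lo) / np.where(span > 0, span, 1.0)
    edges = np.array_split(np.arange(trends.shape[1]), n_bins)
    binmeans = np.column_stack([z[:, e].mean(axis=1) for e in edges])
    above = binmeans > 0.5
    first = np.where(above.any(axis=1), above.argmax(axis=1), -1)
    return np.where(flat, -1, first)


def binned_trends(
    norm: pd.DataFrame,
    pseudotime: np.ndarray,
    n_bins: int = 10,
    equal_count: bool = True,
) -> tuple[pd.DataFrame, pd.Index]:
    """Min-max normalized 10-bin pseudotime trend matrix, activation-ordered.

    Bins are equal-count (quantile) by default.  Constant genes cannot be
    min-max normalized and are excluded with a warning.  Genes are ordered by
    activation bin (first bin whose mean exceeds 0.5), ties broken by the
    interpolated pseudotime of half-maximum.
    """
    pt = np.asarray(pseudotime, dtype=float).ravel()
    if n_bins > len(pt):
        raise ValueError("more bins than cells")
    if equal_count:
        order = np.argsort(pt, kind="stable")
        groups = np.array_split(order, n_bins)
    else:
        edges = np.linspace(pt.min(), pt.max(), n_bins + 1)
        ids = np.clip(np.searchsorted(edges, pt, side="right") - 1, 0, n_bins - 1)
        groups = [np.where(ids == b)[0] for b in range(n_bins)]
    y = norm.to_numpy(dtype=float)
    binned = np.column_stack(
        [y[g].mean(axis=0) if len(g) else np.full(y.shape[1], np.nan) for g in groups]
    )
    lo = np.nanmin(binned, axis=1)
    hi = np.nanmax(binned, axis=1)
    span = hi - lo
    keep = span > 1e-12
    if (~keep).any():
        warnings.warn(f"{(~keep).sum()} constant genes excluded from trend matrix")
    z = (binned[keep] - lo[keep, None]) / span[keep, None]
    genes = norm.columns[keep]
    above = z > 0.5
    act = np.where(above.any(axis=1), above.argmax(axis=1), n_bins)
    # tie-break: interpolated bin position where the trend first crosses 0.5
    half = np.empty(len(genes))
    for i in range(len(genes)):
        j = act[i] if act[i] < n_bins else n_bins - 1
        if j == 0 or not above[i].any():
            half[i] = float(j)
        else:
            y0, y1 = z[i, j - 1], z[i, j]
            half[i] = j - 1 + (0.5 - y0) / max(y1 - y0, 1e-12)
    order = np.lexsort((half, act))
    trend = pd.DataFrame(
        z[order], index=genes[order],
        columns=[f"bin_{b}" for b in range(n_bins)],
    )
    return trend, trend.index


def _leaf_paths(tree: PrincipalTree) -> dict[int, list[int]]:
    """Node paths from the root to every non-root leaf."""
    if tree.root is None:
        raise ValueError("tree has no root selected")
    nbrs: dict[int, list[int]] = {i: [] for i in range(tree.n_nodes)}
    for a, b in tree.edges:
        nbrs[int(a)].append(int(b))
        nbrs[int(b)].append(int(a))
    deg = tree.degrees()
    leaves = [int(v) for v in np.flatnonzero(deg == 1) if v != tree.root]
    paths = {}
    for leaf in leaves:
        # walk from leaf back to root via BFS parents
        parent = {tree.root: None}
        stack = [tree.root]
        while stack:
            u = stack.pop()
            for v in nbrs[u]:
                if v not in parent:
                    parent[v] = u
                    stack.append(v)
        path = [leaf]
        while parent[path[-1]] is not None:
            path.append(parent[path[-1]])
        paths[leaf] = path[::-1]
    return paths


def map_leaves_to_fates(
    tree: PrincipalTree, absorption: pd.DataFrame, n_cells: int = 10
) -> dict[int, str]:
    """Assign each non-root leaf the fate its closest cells are absorbed into."""
    out = {}
    for leaf in _leaf_paths(tree):
        closest = np.argsort(tree.R[:, leaf])[::-1][:n_cells]
        out[leaf] = absorption.iloc[closest].mean(axis=0).idxmax()
    return out


def first_chromaffin_bifurcation(
    tree: PrincipalTree, absorption: pd.DataFrame | None = None
) -> dict:
    """Locate the bifurcation where the two late-splitting fates diverge.

    Of the three fate leaves, the pair whose root-paths share the deepest
    common node is the late-splitting (chromaffin-like) pair; the divergence
    node is the first bifurcation of those fates.  Returns the node, its
    pseudotime, the chromaffin leaf pair and the remaining (glial-like) leaf.
    """
    if tree.bifurcations is None or len(tree.bifurcations) == 0:
        raise ValueError("tree has no bifurcation")
    paths = _leaf_paths(tree)
    leaves = sorted(paths)
    if len(leaves) < 2:
        raise ValueError("tree has fewer than two non-root leaves")
    best = None
    for i, a in enumerate(leaves):
        for b in leaves[i + 1:]:
            shared = 0
            for u, v in zip(paths[a], paths[b]):
                if u != v:
                    break
                shared += 1
            lca = paths[a][shared - 1]
            pt = float(tree.node_pseudotime[lca])
            if best is None or pt > best["pseudotime"]:
                best = {"node": lca, "pseudotime": pt, "pair": (a, b)}
    glial = [l for l in leaves if l not in best["pair"]]
    best["chromaffin_leaves"] = list(best["pair"])
    best["glial_leaf"] = glial[0] if glial else None
    if absorption is not None:
        fates = map_leaves_to_fates(tree, absorption)
        best["chromaffin_fates"] = [fates[l] for l in best["chromaffin_leaves"]]
        best["glial_fate"] = (
            fates[best["glial_leaf"]] if best["glial_leaf"] is not None else None
        )
    return best


def early_path_markers(
    norm: pd.DataFrame,
    tree: PrincipalTree,
    fate: str,
    fdr_cutoff: float = 1.0e-4,
    **assoc_kwargs,
) -> pd.DataFrame:
    """Association test restricted to the early portion of one trajectory.

    Cells are kept when their pseudotime is at most the first chromaffin
    bifurcation and their assigned segment lies on the root-to-fate path
    (``fate`` is "glial" or "chromaffin").  The same test parameters as the
    whole-tree analysis are used.
    """
    if fate not in ("glial", "chromaffin"):
        raise ValueError("fate must be 'glial' or 'chromaffin'")
    bif = first_chromaffin_bifurcation(tree)
    paths = _leaf_paths(tree)
    if fate == "glial":
        if bif["glial_leaf"] is None:
            raise ValueError("no glial-side leaf in this tree")
        path_nodes = set(paths[bif["glial_leaf"]])
    else:
        a, b = bif["chromaffin_leaves"]
        shared = []
        for u, v in zip(paths[a], paths[b]):
            if u != v:
                break
            shared.append(u)
        path_nodes = set(shared)
    argmax_node = tree.R.argmax(axis=1)
    on_path = np.isin(argmax_node, list(path_nodes))
    early = tree.cell_pseudotime <= bif["pseudotime"]
    cells = np.where(on_path & early)[0]
    res = test_association(
        norm, tree.cell_pseudotime, cells=cells, fdr_cutoff=fdr_cutoff,
        **assoc_kwargs,
    )
    res.attrs["cells"] = cells
    res.attrs["bifurcation_pseudotime"] = bif["pseudotime"]
    return res


def test_branch_genes(
    norm: pd.DataFrame,
    tree: PrincipalTree,
    fdr: float = 0.05,
    n_basis: int = 6,
    degree: int = 3,
    lambdas: tuple[float, ...] = _LAMBDA_GRID,
) -> pd.DataFrame:
    """Two-stage branching analysis of the two post-bifurcation branches.

    Stage 1 keeps genes with a positive, BH-significant linear slope of
    expression on pseudotime over progenitor + branch cells (either branch).
    Stage 2 tests the smooth-by-branch interaction by F-test (full
    exp ~ s(pt)*branch against reduced exp ~ s(pt)) on post-bifurcation
    cells; significant genes are assigned to the branch with the larger
    fitted terminal increase.
    """
    bif = first_chromaffin_bifurcation(tree)
    paths = _leaf_paths(tree)
    argmax_node = tree.R.argmax(axis=1)
    pt = tree.cell_pseudotime
    leaf_a, leaf_b = bif["chromaffin_leaves"]
    shared = set()
    for u, v in zip(paths[leaf_a], paths[leaf_b]):
        if u != v:
            break
        shared.add(u)
    prog_cells = np.isin(argmax_node, list(shared))
    branch_cells = {}
    for leaf in (leaf_a, leaf_b):
        post = [nd for nd in paths[leaf] if nd not in shared]
        branch_cells[leaf] = np.isin(argmax_node, post)
        if branch_cells[leaf].sum() < 10:
            raise ValueError(
                f"branch to leaf {leaf} has fewer than 10 cells"
            )
    y = norm.to_numpy(dtype=float)

    # stage 1: linear upregulation along progenitor + branch
    stage1 = {}
    for leaf in (leaf_a, leaf_b):
        mask = prog_cells | branch_cells[leaf]
        t = pt[mask]
        x = np.column_stack([np.ones(mask.sum()), t])
        coef, *_ = np.linalg.lstsq(x, y[mask], rcond=None)
        fitted = x @ coef
        rssf = ((y[mask] - fitted) ** 2).sum(axis=0)
        dfres = mask.sum() - 2
        sxx = ((t - t.mean()) ** 2).sum()
        se = np.sqrt(np.maximum(rssf / dfres / sxx, 1e-300))
        tt = coef[1] / se
        pp = 2.0 * stats.t.sf(np.abs(tt), dfres)
        _, qq, _, _ = multipletests(pp, method="fdr_bh")
        stage1[leaf] = {"slope": coef[1], "p": pp, "q": qq}
    up_any = (
        ((stage1[leaf_a]["slope"] > 0) & (stage1[leaf_a]["q"] < fdr))
        | ((stage1[leaf_b]["slope"] > 0) & (stage1[leaf_b]["q"] < fdr))
    )

    # stage 2: smooth-by-branch interaction on post-bifurcation cells.
    # Each branch's pseudotime is rescaled to [0, 1] over its own span so
    # that both branches cover every time point: without rescaling, genes
    # activating beyond the shorter branch's maximum have no cross-branch
    # contrast and the shared smooth absorbs them.
    post_mask = branch_cells[leaf_a] | branch_cells[leaf_b]
    is_b = branch_cells[leaf_b][post_mask]
    t_resc = np.empty(len(pt))
    for leaf in (leaf_a, leaf_b):
        mask = branch_cells[leaf]
        lo, hi = pt[mask].min(), pt[mask].max()
        t_resc[mask] = (pt[mask] - lo) / max(hi - lo, 1e-12)
    t_post = t_resc[post_mask]
    y_post = y[post_mask]
    b0 = _bspline_design(t_post, n_basis, degree)
    b_full = np.column_stack([b0, b0 * is_b[:, None]])
    d2 = np.diff(np.eye(n_basis), n=2, axis=0)
    blk = d2.T @ d2
    pen_full = np.zeros((2 * n_basis, 2 * n_basis))
    pen_full[:n_basis, :n_basis] = blk
    pen_full[n_basis:, n_basis:] = blk
    # one roughness level, chosen on the reduced (shared-smooth) model and
    # applied to both blocks of the full design, keeps the models nested
    rss_r, edf_r, best_r = _penalized_fits(b0, y_post, lambdas)
    lam_shared = (lambdas[best_r],)
    rss_f, edf_f, best_f = _penalized_fits(
        b_full, y_post, lam_shared, pen=pen_full
    )
    n = post_mask.sum()
    rssr = rss_r[best_r]
    rssf = np.minimum(rss_f[0], rssr)
    df1 = max(edf_f[0] - edf_r[best_r], 1e-8)
    df2 = max(n - edf_f[0], 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fstat = ((rssr - rssf) / df1) / (rssf / df2)
    fstat = np.where(np.isfinite(fstat), np.maximum(fstat, 0.0), 0.0)
    p_int = stats.f.sf(fstat, df1, df2)
    p_int = np.where(up_any, p_int, 1.0)
    _, q_int, _, _ = multipletests(p_int[up_any], method="fdr_bh") if up_any.any() else (
        None, np.ones(0), None, None)
    qfull = np.ones(y.shape[1])
    qfull[up_any] = q_int

    # branch assignment: larger fitted terminal increase
    coef_full = np.linalg.solve(
        b_full.T @ b_full + lam_shared[0] * pen_full
        + 1e-10 * np.eye(2 * n_basis),
        b_full.T @ y_post,
    )
    incr = {}
    for leaf in (leaf_a, leaf_b):
        mask = branch_cells[leaf]
        t = t_resc[mask]
        bm = _bspline_design_like(
            np.array([t.min(), t.max()]), t_post, n_basis, degree
        )
        bm_full = np.column_stack(
            [bm, bm * (1.0 if leaf == leaf_b else 0.0)]
        )
        ends = bm_full @ coef_full
        incr[leaf] = ends[1] - ends[0]
    sig = up_any & (qfull < fdr)
    assigned = np.where(
        sig, np.where(incr[leaf_a] >= incr[leaf_b], f"branch_{leaf_a}",
                      f"branch_{leaf_b}"), "none",
    )
    return pd.DataFrame(
        {
            "slope_a": stage1[leaf_a]["slope"],
            "slope_q_a": stage1[leaf_a]["q"],
            "slope_b": stage1[leaf_b]["slope"],
            "slope_q_b": stage1[leaf_b]["q"],
            "upregulated": up_any,
            "interaction_F": fstat,
            "interaction_p": p_int,
            "interaction_q": qfull,
            "increase_a": incr[leaf_a],
            "increase_b": incr[leaf_b],
            "assigned": assigned,
        },
        index=norm.columns.rename("gene"),
    )
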
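"""End-to-end trajectory pipeline with the study's default parameters.

Chains the stages in their canonical order: QC filter, log10-FPM
normalization, overdispersed-gene selection, PCA/kNN graph (30 PCs, k=15),
Leiden clustering (resolution 1.5), steady-state velocity, 70/30 combined
kernel, terminal-state selection (6 macrostates, 3 terminals), absorption
probabilities, velocity-graph root probabilities, differentiation potential,
fate-simplex embedding, 300-node SimplePPT tree, root selection among tree
tips, pseudotime and branch segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import association as assoc
from . import fate as fate_mod
from . import tree as tree_mod
from .container import CountContainer
from .graph import GraphState, build_graph, cluster_graph
from .qc import QCThresholds, filter_cells, find_overdispersed, normalize_log_fpm
from .velocity import VelocityModel, run_velocity

__all__ = ["TrajectoryResult", "run_trajectory"]


@dataclass
class TrajectoryResult:
    container: CountContainer
    norm: pd.DataFrame
    graph: GraphState
    labels: np.ndarray
    velocity: VelocityModel
    transition: sp.csr_matrix
    terminal: dict[str, np.ndarray]
    absorption: pd.DataFrame
    root_prob: np.ndarray
    potential: pd.Series
    tree: tree_mod.PrincipalTree
    qc_table: pd.DataFrame | None = None
    params: dict = field(default_factory=dict)


def run_trajectory(
    c: CountContainer,
    seed: int = 0,
    qc: QCThresholds | None = None,
    n_pcs: int = 30,
    k: int = 15,
    resolution: float = 1.5,
    w_connectivity: float = 0.30,
    n_macrostates: int = 6,
    n_terminal: int = 3,
    n_nodes: int = 300,
    sigma: float | None = 0.005,
    lam: float = 10.0,
    dp_scale: float = 1.0,
    apply_qc: bool = False,
) -> TrajectoryResult:
    """Run the full default pipeline on a layered count container."""
    qc_table = None
    if apply_qc:
        kept, qc_table = filter_cells(c, qc or QCThresholds())
        c = c.subset_cells(kept)
    norm = normalize_log_fpm(c)
    hv, _ = find_overdispersed(norm)
    g = build_graph(norm, list(hv), n_pcs=n_pcs, k=k, seed=seed)
    labels = cluster_graph(g, resolution, seed=seed)
    vm = run_velocity(c, n_pcs=n_pcs, k=k, seed=seed)
    t_comb = fate_mod.combine_kernels(vm.transition, g, w_connectivity)
    terminal = fate_mod.select_terminal_states(
        t_comb, labels, n_macrostates, n_terminal
    )
    absorption = fate_mod.absorption_probabilities(t_comb, terminal)
    # root cells come from the velocity graph alone: blending in the
    # (symmetric) connectivity kernel flattens the backward stationary
    # distribution over the progenitor pool
    root_prob = fate_mod.root_probabilities(vm.transition)
    dp = fate_mod.differentiation_potential(c, g)
    x = tree_mod.simplex_embedding(absorption, dp.to_numpy(), scale=dp_scale)
    tr = tree_mod.fit_simpleppt(
        x, tree_mod.TreeConfig(n_nodes=n_nodes, sigma=sigma, lam=lam, seed=seed)
    )
    tree_mod.select_root(tr, root_prob, leaves_only=True)
    tree_mod.compute_pseudotime(tr)
    tree_mod.segment_branches(tr)
    return TrajectoryResult(
        container=c, norm=norm, graph=g, labels=labels, velocity=vm,
        transition=t_comb, terminal=terminal, absorption=absorption,
        root_prob=root_prob, potential=dp, tree=tr, qc_table=qc_table,
        params={
            "seed": seed, "n_pcs": n_pcs, "k": k, "resolution": resolution,
            "w_connectivity": w_connectivity, "n_macrostates": n_macrostates,
            "n_terminal": n_terminal, "n_nodes": n_nodes, "sigma": sigma,
            "lam": lam, "dp_scale": dp_scale,
        },
    )


def early_marker_lists(
    res: TrajectoryResult, fdr_cutoff: float = 1.0e-4
) -> dict[str, list[str]]:
    """Significant rising genes along each pre-bifurcation path.

    The association test is two-sided, so the marker list for a fate keeps
    only genes whose fitted trend rises along that path.
    """
    out = {}
    for fate in ("glial", "chromaffin"):
        res_path = assoc.early_path_markers(
            res.norm, res.tree, fate, fdr_cutoff=fdr_cutoff
        )
        out[fate] = list(
            res_path.index[res_path.significant & res_path.rising]
        )
    return out
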
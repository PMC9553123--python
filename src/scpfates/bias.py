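"""Early fate-bias scoring and gene-module repulsion analysis.

Cells are scored against the glial and chromaffin early-marker lists with
expression-matched control sets; a cell is assigned a fate when that score
is strictly above zero AND strictly above the other score, otherwise it
remains an (unbiased) SCP.  Within SCP-assigned cells the two modules are
examined by local gene-gene Pearson correlation: mean intra-module and
inter-module correlations, a repulsion score contrasting the two, and the
top-4 genes per module by own-module coordination minus cross-module
correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scoring import score_gene_set

__all__ = ["FateBiasScores", "ModuleRepulsion", "score_fate_bias", "module_correlations"]


@dataclass
class FateBiasScores:
    table: pd.DataFrame  # per cell: glial_score, chc_score, assignment

    @property
    def assignment(self) -> pd.Series:
        return self.table["assignment"]


@dataclass
class ModuleRepulsion:
    correlations: pd.DataFrame      # gene x gene local Pearson, SCP cells only
    gene_stats: pd.DataFrame        # per gene: module, intra_mean, cross_mean
    intra_a: float
    intra_b: float
    inter: float
    repulsion: float
    top_genes: dict[str, list[str]] = field(default_factory=dict)


def score_fate_bias(
    norm: pd.DataFrame,
    glial_genes: list[str],
    chc_genes: list[str],
    seed: int = 0,
    n_bins: int = 25,
    ctrl_size: int = 50,
) -> FateBiasScores:
    """Score and assign each cell to glial-biased, chromaffin-biased or SCP.

    Assignment requires the winning score to be > 0 and strictly greater
    than the other score; ties and all-nonpositive cases stay SCP.
    """
    if not glial_genes or not chc_genes:
        raise ValueError("both marker lists must be non-empty")
    g = score_gene_set(norm, glial_genes, "glial", n_bins, ctrl_size, seed).scores
    c = score_gene_set(norm, chc_genes, "chromaffin", n_bins, ctrl_size, seed + 1).scores
    gv, cv = g.to_numpy(), c.to_numpy()
    assignment = np.where(
        (gv > 0) & (gv > cv), "glial-biased",
        np.where((cv > 0) & (cv > gv), "chromaffin-biased", "SCP"),
    )
    return FateBiasScores(
        table=pd.DataFrame(
            {"glial_score": gv, "chc_score": cv, "assignment": assignment},
            index=norm.index,
        )
    )


def module_correlations(
    norm: pd.DataFrame,
    scp_cells: np.ndarray,
    module_a: list[str],
    module_b: list[str],
    min_cells: int = 10,
) -> ModuleRepulsion:
    """Local gene-gene Pearson correlations of two modules over SCP cells.

    intra means average all unordered within-module pairs; inter averages all
    A x B pairs; repulsion = (intra_A + intra_B)/2 - inter.  Genes with zero
    variance among the SCP cells are excluded with a warning.  Top-4 genes
    per module maximize own-module mean correlation minus cross-module mean.
    """
    if set(module_a) & set(module_b):
        raise ValueError("modules must be disjoint")
    scp_cells = np.asarray(scp_cells)
    sub = norm.iloc[scp_cells] if scp_cells.dtype != bool else norm.loc[scp_cells]
    if sub.shape[0] < min_cells:
        raise ValueError(f"need at least {min_cells} SCP cells")
    genes = [g for g in list(module_a) + list(module_b) if g in norm.columns]
    x = sub[genes].to_numpy(dtype=float)
    sd = x.std(axis=0)
    keep = sd > 0
    if (~keep).any():
        dropped = [g for g, k in zip(genes, keep) if not k]
        warnings.warn(f"zero-variance genes excluded: {dropped}")
    genes = [g for g, k in zip(genes, keep) if k]
    a = [g for g in module_a if g in genes]
    b = [g for g in module_b if g in genes]
    corr = pd.DataFrame(
        np.corrcoef(sub[genes].to_numpy(dtype=float), rowvar=False),
        index=genes, columns=genes,
    )

    def pair_mean_within(mod: list[str]) -> float:
        if len(mod) < 2:
            return float("nan")
        m = corr.loc[mod, mod].to_numpy()
        iu = np.triu_indices(len(mod), k=1)
        return float(m[iu].mean())

    intra_a = pair_mean_within(a)
    intra_b = pair_mean_within(b)
    inter = float(corr.loc[a, b].to_numpy().mean()) if a and b else float("nan")
    repulsion = 0.5 * (intra_a + intra_b) - inter

    rows = []
    for g in a:
        own = [h for h in a if h != g]
        rows.append((g, "A", float(corr.loc[g, own].mean()) if own else np.nan,
                     float(corr.loc[g, b].mean()) if b else np.nan))
    for g in b:
        own = [h for h in b if h != g]
        rows.append((g, "B", float(corr.loc[g, own].mean()) if own else np.nan,
                     float(corr.loc[g, a].mean()) if a else np.nan))
    stats = pd.DataFrame(
        rows, columns=["gene", "module", "intra_mean", "cross_mean"]
    ).set_index("gene")
    stats["separation"] = stats["intra_mean"] - stats["cross_mean"]
    top = {
        "A": stats[stats.module == "A"]["separation"].nlargest(4).index.tolist(),
        "B": stats[stats.module == "B"]["separation"].nlargest(4).index.tolist(),
    }
    return ModuleRepulsion(
        correlations=corr, gene_stats=stats,
        intra_a=intra_a, intra_b=intra_b, inter=inter,
        repulsion=float(repulsion), top_genes=top,
    )
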
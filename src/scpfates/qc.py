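"""Cell filtering, library-size normalization and overdispersed-gene selection.

QC keeps cells that satisfy all three SmartSeq2 quality conditions strictly:
more than 5e4 transcripts, more than 3000 detected genes, and an ERCC read
fraction below 25%.  Expression is normalized per cell to fragments-per-
million over non-ERCC genes and log10(x+1)-transformed.  Overdispersed genes
are called from the residuals of a smooth mean–variance trend on log scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .container import CountContainer

__all__ = ["QCThresholds", "filter_cells", "normalize_log_fpm", "find_overdispersed"]


@dataclass(frozen=True)
class QCThresholds:
    min_transcripts: float = 5.0e4
    min_genes: int = 3000
    max_ercc_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.min_transcripts <= 0 or self.min_genes <= 0:
            raise ValueError("QC thresholds must be positive")
        if not 0.0 < self.max_ercc_fraction <= 1.0:
            raise ValueError("max_ercc_fraction must lie in (0, 1]")


def filter_cells(
    c: CountContainer, th: QCThresholds = QCThresholds()
) -> tuple[np.ndarray, pd.DataFrame]:
    """Strict three-way QC filter on the total layer.

    A cell is kept iff transcripts > min_transcripts AND detected genes >
    min_genes AND ERCC fraction < max_ercc_fraction (all strict).  Returns the
    kept cell positions and a QC table reporting the three metrics and the
    keep flag for every input cell.
    """
    total = c.layer("total")
    cellular = total[:, ~c.ercc]
    spike = total[:, c.ercc]
    transcripts = np.asarray(cellular.sum(axis=1)).ravel()
    genes = np.asarray((cellular > 0).sum(axis=1)).ravel()
    spike_sum = np.asarray(spike.sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        ercc_frac = np.where(
            transcripts + spike_sum > 0,
            spike_sum / np.maximum(transcripts + spike_sum, 1),
            1.0,
        )
    keep = (
        (transcripts > th.min_transcripts)
        & (genes > th.min_genes)
        & (ercc_frac < th.max_ercc_fraction)
    )
    table = pd.DataFrame(
        {
            "transcripts": transcripts,
            "detected_genes": genes,
            "ercc_fraction": ercc_frac,
            "keep": keep,
        },
        index=pd.Index(c.cell_ids, name="cell_id"),
    )
    return np.where(keep)[0], table


def normalize_log_fpm(c: CountContainer, layer: str = "total") -> pd.DataFrame:
    """Per-cell fragments-per-million over non-ERCC genes, then log10(x+1).

    ERCC genes are excluded from both the library-size denominator and the
    output.  A cell with zero non-ERCC counts is an error (it cannot be
    normalized), reported by id.
    """
    mat = np.asarray(c.layer(layer).todense(), dtype=float)[:, ~c.ercc]
    lib = mat.sum(axis=1)
    empty = np.where(lib == 0)[0]
    if empty.size:
        raise ValueError(
            f"cell {c.cell_ids[empty[0]]!r} has zero non-ERCC counts; "
            "filter before normalizing"
        )
    fpm = mat * (1.0e6 / lib[:, None])
    return pd.DataFrame(
        np.log10(fpm + 1.0),
        index=pd.Index(c.cell_ids, name="cell_id"),
        columns=pd.Index(c.gene_ids[~c.ercc], name="gene"),
    )


def find_overdispersed(
    norm: pd.DataFrame,
    fpr: float = 0.02,
    lowess_frac: float = 0.3,
) -> tuple[pd.Index, pd.DataFrame]:
    """Select genes whose variance exceeds the smooth mean–variance trend.

    Per gene the log variance of the normalized expression is regressed on the
    log mean with LOWESS; residuals are robust-standardized (median/MAD) and a
    gene is selected when its z-score exceeds the upper-``fpr`` normal
    quantile.  Constant genes are never selected.  Fully deterministic.

    Returns the selected gene index and a per-gene table with columns
    mean, var, residual, z, selected (z is NaN for zero-variance genes, which
    rank last).
    """
    if norm.shape[0] < 2:
        raise ValueError("need at least 2 cells to estimate dispersion")
    if norm.shape[1] < 10:
        raise ValueError("need at least 10 genes to fit a mean-variance trend")
    x = norm.to_numpy()
    mean = x.mean(axis=0)
    var = x.var(axis=0, ddof=1)
    ok = var > 0
    logm = np.log(mean[ok] + 1e-10)
    logv = np.log(var[ok])
    fit = lowess(logv, logm, frac=lowess_frac, return_sorted=False)
    resid = logv - fit
    mad = np.median(np.abs(resid - np.median(resid)))
    scale = max(1.4826 * mad, 1e-12)
    z = (resid - np.median(resid)) / scale
    zfull = np.full(norm.shape[1], np.nan)
    zfull[ok] = z
    rfull = np.full(norm.shape[1], np.nan)
    rfull[ok] = resid
    cut = stats.norm.ppf(1.0 - fpr)
    selected = np.zeros(norm.shape[1], dtype=bool)
    selected[ok] = z > cut
    table = pd.DataFrame(
        {
            "mean": mean,
            "var": var,
            "residual": rfull,
            "z": zfull,
            "selected": selected,
        },
        index=norm.columns,
    )
    return norm.columns[selected], table
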
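"""Summary-statistics tests for imaging-based validation counts.

Marker-positive cell proportions are reported per animal as percentages; each
developmental-stage group is summarized as mean ± SEM over n animals, and
stages are compared with a two-tailed pooled-variance Student t-test computed
directly from those summaries (SD_i = SEM_i * sqrt(n_i), df = n1 + n2 - 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["SummaryGroup", "TTestResult", "ttest_from_summary", "summarize_proportions"]


@dataclass(frozen=True)
class SummaryGroup:
    """mean ± SEM summary of percent-positive cells over n animals."""

    label: str
    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("summary group needs n >= 2 animals")
        if self.sem < 0:
            raise ValueError("SEM must be nonnegative")
        if not 0.0 <= self.mean <= 100.0:
            raise ValueError("mean percentage must lie in [0, 100]")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    degenerate: bool = False  # SE == 0 with unequal means


def ttest_from_summary(g1: SummaryGroup, g2: SummaryGroup) -> TTestResult:
    """Two-tailed pooled Student t-test from group means, SEMs and sizes.

    With n1 == n2 the pooled standard error reduces to
    sqrt(SEM1**2 + SEM2**2).
    """
    sd1 = g1.sem * np.sqrt(g1.n)
    sd2 = g2.sem * np.sqrt(g2.n)
    df = g1.n + g2.n - 2
    sp2 = ((g1.n - 1) * sd1**2 + (g2.n - 1) * sd2**2) / df
    se = np.sqrt(sp2) * np.sqrt(1.0 / g1.n + 1.0 / g2.n)
    if se == 0.0:
        if g1.mean == g2.mean:
            return TTestResult(t=0.0, df=df, p=1.0)
        return TTestResult(t=np.inf if g1.mean > g2.mean else -np.inf, df=df,
                           p=0.0, degenerate=True)
    t = (g1.mean - g2.mean) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=df, p=float(p))


def summarize_proportions(positive: np.ndarray, total: np.ndarray,
                          label: str = "") -> SummaryGroup:
    """Per-animal percent positive -> group mean and SEM (SD/sqrt(n))."""
    positive = np.asarray(positive, dtype=float)
    total = np.asarray(total, dtype=float)
    if np.any(total <= 0):
        raise ValueError("every animal must have a positive cell total")
    if positive.shape != total.shape:
        raise ValueError("positive and total must have matching shapes")
    pct = 100.0 * positive / total
    n = pct.size
    if n < 2:
        raise ValueError("SEM undefined for a single animal (need n >= 2)")
    mean = float(np.mean(pct))
    sem = float(np.std(pct, ddof=1) / np.sqrt(n))
    return SummaryGroup(label=label, mean=mean, sem=sem, n=n)
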
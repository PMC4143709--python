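"""Method-comparison harness: ROC curves, replicate averaging, AUC tests.

The ROC conventions follow the gene-screening setting: each gene carries
a significance score (smaller = more significant, typically a p-value)
and a causal/noncausal truth flag; sweeping a significance threshold,
fpr is the fraction of true noncausal genes claimed and tpr the fraction
of true causal genes claimed.  Ties in scores are claimed together.
Per-replicate curves are averaged vertically (tpr at fixed fpr) and AUCs
compared across replicates with a paired Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["RocCurve", "roc_from_scores", "average_roc", "compare_auc"]


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    method: str = ""
    replicate: int | str | None = None

    def __post_init__(self) -> None:
        self.fpr = np.asarray(self.fpr, dtype=float)
        self.tpr = np.asarray(self.tpr, dtype=float)
        if self.fpr.shape != self.tpr.shape:
            raise ValueError("fpr and tpr must have the same length")
        if np.any(np.diff(self.fpr) < 0) or np.any(np.diff(self.tpr) < 0):
            raise ValueError("fpr and tpr must be nondecreasing")


def roc_from_scores(scores, causal, *, method: str = "",
                    replicate=None) -> RocCurve:
    """ROC of per-gene significance scores against causal-gene truth.

    ``scores``: smaller = more significant; NaN (method failed on that
    gene) ranks last, i.e. least significant.  ``causal``: boolean flags.
    The curve starts at (0, 0), ends at (1, 1), and AUC is the trapezoid
    area.
    """
    s = np.asarray(scores, dtype=float)
    c = np.asarray(causal, dtype=bool)
    if s.shape != c.shape or s.ndim != 1:
        raise ValueError("scores and causal flags must be aligned vectors")
    n_causal = int(c.sum())
    n_noncausal = int((~c).sum())
    if n_causal == 0 or n_noncausal == 0:
        raise ValueError("need at least one causal and one noncausal gene")
    s = np.where(np.isnan(s), np.inf, s)

    order = np.argsort(s, kind="mergesort")
    s_sorted = s[order]
    c_sorted = c[order]
    # group ties: indices of the last element of each tie block
    last_of_block = np.flatnonzero(np.r_[s_sorted[1:] != s_sorted[:-1], True])
    cum_causal = np.cumsum(c_sorted)
    cum_total = np.arange(1, len(s) + 1)
    tp = cum_causal[last_of_block]
    fp = cum_total[last_of_block] - tp
    tpr = np.r_[0.0, tp / n_causal]
    fpr = np.r_[0.0, fp / n_noncausal]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, auc=auc, method=method,
                    replicate=replicate)


def average_roc(curves: Sequence[RocCurve],
                grid: np.ndarray | None = None) -> RocCurve:
    """Vertical average of per-replicate ROC curves.

    Each curve's tpr is interpolated on a fixed fpr grid (0, 0.01, .., 1
    by default) and averaged pointwise; the reported AUC is the trapezoid
    area of the averaged curve.
    """
    if len(curves) < 2:
        raise ValueError("need at least 2 curves to average")
    if grid is None:
        grid = np.linspace(0.0, 1.0, 101)
    tprs = []
    for cv in curves:
        # keep the max tpr at duplicate fpr values so interp sees a function
        fpr = np.unique(cv.fpr)
        tpr = np.asarray([cv.tpr[cv.fpr == f].max() for f in fpr])
        tprs.append(np.interp(grid, fpr, tpr))
    mean_tpr = np.mean(tprs, axis=0)
    auc = float(np.trapezoid(mean_tpr, grid))
    method = curves[0].method
    return RocCurve(fpr=grid, tpr=mean_tpr, auc=auc, method=method,
                    replicate="average")


def compare_auc(auc_a, auc_b) -> float:
    """Two-sided paired Wilcoxon signed-rank p for per-replicate AUCs.

    Zero differences are dropped (Wilcoxon's rule); the exact null
    distribution is used for 25 or fewer nonzero pairs, the normal
    approximation above.  All-zero differences give p = 1.
    """
    a = np.asarray(auc_a, dtype=float)
    b = np.asarray(auc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired AUC vectors must be aligned")
    if len(a) < 5:
        raise ValueError("need at least 5 paired replicates")
    d = a - b
    nz = d[d != 0]
    if nz.size == 0:
        return 1.0
    mode = "exact" if nz.size <= 25 else "approx"
    try:
        res = stats.wilcoxon(nz, zero_method="wilcox", correction=False,
                             alternative="two-sided", method=mode)
    except ValueError:
        res = stats.wilcoxon(nz, zero_method="wilcox", correction=False,
                             alternative="two-sided", method="approx")
    return float(res.pvalue)
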
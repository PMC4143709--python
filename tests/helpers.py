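"""Independent oracle implementations used by the test suite.

Everything here is deliberately coded along a different route than the
package (exact rational algebra, per-step global evaluation, explicit
enumeration) so that agreement is evidence, not tautology.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations

import numpy as np


# ----------------------------------------------------------------------
# Per-SNP similarity: alternative algebraic forms, exact rationals
# ----------------------------------------------------------------------

def similarity_case_oracle(p: Fraction) -> dict[tuple[int, int], Fraction]:
    """Single-fraction closed forms of the six genotype-pair cases.

    Each is the production table's case rewritten over a common
    denominator, evaluated in exact rational arithmetic.
    """
    q = 1 - p
    return {
        (0, 0): 2 * p ** 2,
        (1, 1): (q - p) ** 2 / (2 * p ** 2 * q ** 2),   # = 1/2 (1/p - 1/q)^2
        (2, 2): 2 * q ** 2,
        (0, 1): (2 * p - q) / (2 * p * q ** 2),
        (0, 2): Fraction(-1) / (p * q),
        (1, 2): (2 * q - p) / (2 * p ** 2 * q),
    }


# ----------------------------------------------------------------------
# Ward clustering: exhaustive per-step cost evaluation from the
# ORIGINAL distances (centroid identity), no Lance-Williams recursion
# ----------------------------------------------------------------------

def ward_bruteforce(dm: np.ndarray) -> np.ndarray:
    """Greedy Ward agglomeration evaluating every cluster pair's merge
    cost from the original squared distances at every step.

    cost(A, B) = 2 |A||B| / (|A|+|B|) * ||c_A - c_B||^2 with the
    centroid gap taken from pairwise squared distances:
    ||c_A - c_B||^2 = mean d2(A, B) - mean d2(A, A)/2 - mean d2(B, B)/2.
    Heights are sqrt(cost); ties broken by smallest (min id, max id).
    Returns a scipy-style linkage matrix.
    """
    d2 = np.asarray(dm, dtype=float) ** 2
    n = d2.shape[0]
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    out = np.empty((n - 1, 4))
    for step in range(n - 1):
        best = None
        for a, b in combinations(sorted(members), 2):
            A, B = members[a], members[b]
            gap = (d2[np.ix_(A, B)].mean()
                   - d2[np.ix_(A, A)].mean() / 2.0
                   - d2[np.ix_(B, B)].mean() / 2.0)
            cost = 2.0 * len(A) * len(B) / (len(A) + len(B)) * gap
            key = (cost, a, b)
            if best is None or key < best:
                best = key
        cost, a, b = best
        out[step] = (a, b, np.sqrt(max(cost, 0.0)), len(members[a]) + len(members[b]))
        members[n + step] = members.pop(a) + members.pop(b)
    return out


# ----------------------------------------------------------------------
# Association statistics: direct group-sum formulas
# ----------------------------------------------------------------------

def pr_bruteforce(y: np.ndarray, labels: np.ndarray) -> float:
    y = np.asarray(y, dtype=float)
    n = len(y)
    ybar = y.sum() / n
    s2 = ((y - ybar) ** 2).sum() / n
    total = 0.0
    for g in np.unique(labels):
        yg = y[labels == g]
        ni = len(yg)
        total += ni * (yg.mean() - ybar) ** 2 / (s2 / ni)
    return total


def anova_f_bruteforce(y: np.ndarray, labels: np.ndarray) -> float:
    y = np.asarray(y, dtype=float)
    groups = np.unique(labels)
    n, k = len(y), len(groups)
    ssb = sum(len(y[labels == g]) * (y[labels == g].mean() - y.mean()) ** 2
              for g in groups)
    ssw = sum(((y[labels == g] - y[labels == g].mean()) ** 2).sum()
              for g in groups)
    return (ssb / (k - 1)) / (ssw / (n - k))


# ----------------------------------------------------------------------
# ROC: explicit confusion matrix at every threshold
# ----------------------------------------------------------------------

def roc_bruteforce(scores: np.ndarray, causal: np.ndarray):
    """All-thresholds confusion-matrix sweep; returns (fpr, tpr, auc)."""
    s = np.where(np.isnan(scores), np.inf, np.asarray(scores, dtype=float))
    c = np.asarray(causal, dtype=bool)
    pts = [(0.0, 0.0)]
    for t in np.unique(s):
        claimed = s <= t
        tp = int((claimed & c).sum())
        fp = int((claimed & ~c).sum())
        pts.append((fp / (~c).sum(), tp / c.sum()))
    fpr = np.array([p[0] for p in pts])
    tpr = np.array([p[1] for p in pts])
    return fpr, tpr, float(np.trapezoid(tpr, fpr))


# ----------------------------------------------------------------------
# Paired Wilcoxon signed-rank: full sign enumeration (exact, small n)
# ----------------------------------------------------------------------

def wilcoxon_exact_enum(diffs: np.ndarray) -> float:
    """Two-sided exact signed-rank p by enumerating all 2^n sign vectors.

    Zeros dropped; assumes untied absolute values (continuous inputs).
    p = min(1, 2 * min(P(W+ <= w), P(W+ >= w))).
    """
    from scipy.stats import rankdata

    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0
    r = rankdata(np.abs(d))
    w_obs = r[d > 0].sum()
    sums = np.zeros(1)
    for ri in r:
        sums = np.concatenate([sums, sums + ri])
    le = np.mean(sums <= w_obs + 1e-9)
    ge = np.mean(sums >= w_obs - 1e-9)
    return float(min(1.0, 2.0 * min(le, ge)))
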
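"""Ward hierarchical clustering on precomputed distances, and tree cutting.

Used in two modes: genotype distances (one tree per gene, cut into
k in [5, 10] groups, default 10) and longitudinal trait trajectories
(Euclidean distances between adjusted per-subject trait vectors, cut into
2 groups interpretable as high/low trait).

The linkage is the Lance-Williams Ward update applied directly to the
supplied dissimilarities (the "Ward on dissimilarities" convention: raw
distances in, updated as Ward D2, merge heights on the raw-distance
scale, matching ``scipy``'s ``ward``/R's ``hclust(ward.D2)``).  Ties are
broken deterministically: among minimal-cost pairs, merge the pair whose
(min cluster id, max cluster id) is lexicographically smallest, with
scipy-style ids (originals 0..n-1, then n+step for each merge).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist, squareform

from .panels import TraitPanel
from .similarity import DistanceMatrix

__all__ = [
    "Dendrogram",
    "Partition",
    "ward_linkage",
    "cut_tree",
    "cluster_genotypes",
    "cluster_phenotypes",
]


@dataclass
class Dendrogram:
    """Agglomeration history in scipy linkage format.

    ``linkage`` is an ``(n-1, 4)`` array: merged cluster ids (originals
    ``0..n-1``, merge ``j`` creating id ``n+j``), merge height, and the
    size of the newly formed cluster.
    """

    linkage: np.ndarray
    n_leaves: int

    def __post_init__(self) -> None:
        self.linkage = np.asarray(self.linkage, dtype=float)
        if self.linkage.shape != (self.n_leaves - 1, 4):
            raise ValueError("linkage must have n-1 rows of 4 columns")

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def leaf_order(self) -> np.ndarray:
        return np.asarray(sch.leaves_list(self.linkage), dtype=int)


@dataclass
class Partition:
    """Assignment of each subject to one of k groups, with provenance.

    Labels are canonical: group 1 is the group containing the first
    subject, then groups are numbered in order of first appearance.
    """

    labels: np.ndarray
    k: int
    source: str = ""
    group_means: dict[int, float] | None = field(default=None)
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        sizes = np.bincount(self.labels, minlength=self.k + 1)[1:self.k + 1]
        if len(np.unique(self.labels)) != self.k or np.any(sizes == 0):
            raise ValueError("every group in 1..k must be nonempty")

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k + 1)[1:]

    @property
    def high_group(self) -> int:
        """Group label with the larger mean outcome (phenotype mode only)."""
        if not self.group_means:
            raise ValueError("partition carries no group means")
        return max(self.group_means, key=self.group_means.get)


def _canonical(labels: np.ndarray) -> np.ndarray:
    """Relabel groups 1..k in order of first appearance."""
    out = np.empty(len(labels), dtype=int)
    seen: dict[int, int] = {}
    for i, lab in enumerate(labels):
        lab = int(lab)
        if lab not in seen:
            seen[lab] = len(seen) + 1
        out[i] = seen[lab]
    return out


# ----------------------------------------------------------------------
# Linkage
# ----------------------------------------------------------------------

def ward_linkage(D) -> Dendrogram:
    """Ward agglomeration of a precomputed distance matrix.

    Greedy: each step merges the active pair with the smallest Ward
    merge distance, maintained by the Lance-Williams recursion on squared
    distances; the recorded height is the square root (Ward D2).
    """
    dm = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    n = dm.shape[0]
    if dm.ndim != 2 or dm.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if not np.all(np.isfinite(dm)):
        raise ValueError("distances must be finite")

    w = dm.astype(float) ** 2          # working Ward distances (squared)
    np.fill_diagonal(w, np.inf)
    sizes = np.ones(n)
    ids = np.arange(n)                  # scipy-style id living in each slot
    active = np.ones(n, dtype=bool)
    out = np.empty((n - 1, 4))
    # cached per-row minimum and its column, kept exact across updates
    rowmin = w.min(axis=1)
    nn = w.argmin(axis=1)

    for step in range(n - 1):
        r = int(np.argmin(rowmin))
        h2 = rowmin[r]
        tied_rows = np.flatnonzero(rowmin == h2)
        if len(tied_rows) == 1 and np.count_nonzero(w[r] == h2) == 1:
            i, j = r, int(nn[r])
        else:  # pick the tied pair with lexicographically smallest ids
            sub = np.argwhere(w[tied_rows] == h2)
            cand_i = tied_rows[sub[:, 0]]
            cand_j = sub[:, 1]
            ia, ib = ids[cand_i], ids[cand_j]
            lo, hi = np.minimum(ia, ib), np.maximum(ia, ib)
            best = int(np.argmin(lo.astype(np.int64) * (2 * n) + hi))
            i, j = int(cand_i[best]), int(cand_j[best])
        if i > j:
            i, j = j, i
        ida, idb = int(ids[i]), int(ids[j])
        sa, sb = sizes[i], sizes[j]
        out[step] = (min(ida, idb), max(ida, idb), np.sqrt(max(h2, 0.0)), sa + sb)

        active[j] = False
        xs = np.flatnonzero(active)
        xs = xs[xs != i]
        sx = sizes[xs]
        newrow = ((sa + sx) * w[i, xs] + (sb + sx) * w[j, xs] - sx * h2) \
            / (sa + sb + sx)
        w[i, xs] = newrow
        w[xs, i] = newrow
        w[j, :] = np.inf
        w[:, j] = np.inf
        sizes[i] = sa + sb
        ids[i] = n + step
        rowmin[j] = np.inf

        if len(xs):
            # rows whose cached minimum might have changed
            improved = newrow <= rowmin[xs]
            rowmin[xs[improved]] = newrow[improved]
            nn[xs[improved]] = i
            stale = xs[~improved & ((nn[xs] == i) | (nn[xs] == j))]
            if len(stale):
                rowmin[stale] = w[stale].min(axis=1)
                nn[stale] = w[stale].argmin(axis=1)
            rowmin[i] = w[i].min()
            nn[i] = w[i].argmin()
        else:
            rowmin[i] = np.inf

    return Dendrogram(linkage=out, n_leaves=n)


def cut_tree(tree: Dendrogram, k: int, *, source: str = "") -> Partition:
    """Partition obtained by undoing the last k-1 merges; canonical labels.

    Cutting follows the merge order directly (not the heights), so tied
    merges whose recorded heights differ by float dust cannot change the
    group count.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    parent = np.arange(2 * n - 1)
    for step in range(n - k):  # apply the first n-k merges
        a, b = int(tree.linkage[step, 0]), int(tree.linkage[step, 1])
        parent[a] = parent[b] = n + step
    # resolve roots top-down so every lookup is a single hop
    for node in range(2 * n - 2, -1, -1):
        parent[node] = parent[parent[node]]
    raw = parent[:n]
    labels = _canonical(raw)
    return Partition(labels=labels, k=k, source=source)


def cluster_genotypes(D, k: int = 10) -> Partition:
    """Genotype-side clustering: Ward on the gene's distance matrix, cut at k.

    Partition sizes 5-10 are the studied range (default 10); other values
    are allowed but flagged with a warning.
    """
    if not 5 <= k <= 10:
        warnings.warn(f"k={k} lies outside the studied range [5, 10]",
                      stacklevel=2)
    tree = ward_linkage(D)
    return cut_tree(tree, k, source="genotype")


def cluster_phenotypes(traits: TraitPanel, *, k: int = 2,
                       metric: str = "euclidean") -> Partition:
    """Phenotype-side clustering of adjusted trait trajectories.

    Ward linkage on Euclidean distances between the T-dimensional
    covariate-adjusted trajectory vectors, cut at ``k`` (default 2, the
    high/low split).  Group means of the trajectory average are attached
    so callers can identify the "high" group.  An all-zero-height tree
    (identical subjects) still returns k nonempty groups, tie-broken
    deterministically, and is flagged ``degenerate``.
    """
    if traits.adjusted is None:
        raise ValueError("traits must be covariate-adjusted first "
                         "(run adjust_covariates)")
    vecs = np.asarray(traits.adjusted, dtype=float)
    if np.any(~np.isfinite(vecs)):
        raise ValueError("adjusted trait vectors contain missing values; "
                         "run assemble_vectors first")
    dm = squareform(pdist(vecs, metric=metric))
    tree = ward_linkage(dm)
    part = cut_tree(tree, k, source="phenotype")
    part.degenerate = bool(np.all(tree.heights == 0.0))
    traj_mean = vecs.mean(axis=1)
    part.group_means = {
        g: float(traj_mean[part.labels == g].mean()) for g in range(1, k + 1)
    }
    return part
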
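"""Inverse-probability-weighted genotype similarity and distances.

The per-SNP score between two subjects depends only on the unordered pair
of minor-allele counts (g_i, g_j) and the SNP's observed minor allele
frequency p.  Matches that are improbable under Hardy-Weinberg (sharing a
rare allele) score high, matches on the common homozygote score near
zero, and strongly discordant pairs (0 vs 2) score negative — so rare
variants dominate the gene-level similarity.

The six case coefficients live in one table-driven function
(:func:`_score_cases`) so that correcting any coefficient is a one-line
change re-verified by the whole suite.  Scores are evaluated in exact
rational arithmetic (on the exact binary value of ``p``) and rounded once
to float; this makes the table bit-reproducible and directly comparable
to a symbolic oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .panels import GenotypePanel

__all__ = [
    "SimilarityMatrix",
    "DistanceMatrix",
    "fold_and_maf",
    "snp_similarity",
    "snp_score_table",
    "gene_similarity",
    "similarity_to_distance",
    "filter_snps_by_maf",
    "panel_from_dosage",
]


@dataclass
class SimilarityMatrix:
    """Symmetric subjects x subjects similarity for one gene."""

    gene: str
    values: np.ndarray
    n_snps_used: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not np.all(np.isfinite(v)):
            raise ValueError("similarity matrix must be finite")
        if not np.array_equal(v, v.T):
            raise ValueError("similarity matrix must be symmetric")
        self.values = v

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative subjects x subjects distances, zero diagonal."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.all(np.isfinite(v)):
            raise ValueError("distance matrix must be finite")
        if np.any(v < 0):
            raise ValueError("distances must be nonnegative")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance diagonal must be zero")
        self.values = v

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]


# ----------------------------------------------------------------------
# Eq.-style case table
# ----------------------------------------------------------------------

def _score_cases(p: Fraction) -> dict[tuple[int, int], Fraction]:
    """Exact case table for the per-SNP score at minor allele frequency p.

    Keys are unordered genotype pairs (g_low, g_high).  This is the single
    auditable home of the coefficients.
    """
    one = Fraction(1)
    half = Fraction(1, 2)
    q = one - p
    cross = one / (p * q)          # 1 / (p (1-p))
    return {
        (0, 0): 2 * p * p,
        (1, 1): half * (one / p ** 2 + one / q ** 2) - cross,
        (2, 2): 2 * q * q,
        (0, 1): one / q ** 2 - half * cross,
        (0, 2): -cross,
        (1, 2): one / p ** 2 - half * cross,
    }


def _check_p(p: float) -> Fraction:
    if not np.isfinite(p) or not (0.0 < p <= 0.5):
        raise ValueError(f"minor allele frequency must lie in (0, 0.5], got {p}")
    return Fraction(p)  # exact binary value of the float


def snp_similarity(g_i: int, g_j: int, p: float) -> float:
    """Inverse-probability-weighted score for one SNP and one subject pair.

    ``g_i, g_j`` are minor-allele counts in {0, 1, 2}; ``p`` the SNP's
    observed MAF in (0, 0.5].  Symmetric in (g_i, g_j).
    """
    for g in (g_i, g_j):
        if g != int(g):
            raise ValueError("genotypes must be integers in {0,1,2}; "
                             "round dosages upstream")
        if not 0 <= int(g) <= 2:
            raise ValueError(f"genotype out of range: {g}")
    pf = _check_p(float(p))
    a, b = sorted((int(g_i), int(g_j)))
    return float(_score_cases(pf)[(a, b)])


def snp_score_table(p: float) -> np.ndarray:
    """3x3 score lookup table T with T[g_i, g_j] = per-SNP score."""
    cases = _score_cases(_check_p(float(p)))
    t = np.empty((3, 3))
    for (a, b), v in cases.items():
        t[a, b] = t[b, a] = float(v)
    return t


# ----------------------------------------------------------------------
# Folding / panel construction
# ----------------------------------------------------------------------

def fold_and_maf(dosage_column: np.ndarray):
    """Round a dosage column to genotypes, fold to the minor allele.

    Returns ``(recoded, maf)`` where ``recoded`` counts the minor allele,
    or ``(None, nan)`` for a monomorphic (constant) column, which must be
    excluded — the score's division by p or 1-p would be undefined.
    Dosage ties at .5 round half-up; missing values are imputed to the
    column's modal genotype (with a warning).
    """
    col = np.asarray(dosage_column, dtype=float)
    if np.any(np.isfinite(col) & ((col < 0) | (col > 2))):
        raise ValueError("dosages must lie in [0, 2]")
    g = np.floor(col + 0.5)  # round half-up
    miss = ~np.isfinite(g)
    if miss.any():
        if miss.all():
            return None, float("nan")
        vals, counts = np.unique(g[~miss], return_counts=True)
        g[miss] = vals[np.argmax(counts)]
        warnings.warn(f"imputed {int(miss.sum())} missing dosages to the "
                      "modal genotype", stacklevel=2)
    g = g.astype(np.int8)
    if np.all(g == g[0]):
        return None, float("nan")
    freq = g.sum() / (2 * len(g))
    if freq > 0.5:
        g = 2 - g
        freq = 1.0 - freq
    return g, float(freq)


def panel_from_dosage(dosage, snps, subjects=None) -> GenotypePanel:
    """Build a :class:`GenotypePanel` from a subjects x SNPs dosage matrix.

    Columns are rounded and folded with :func:`fold_and_maf`; monomorphic
    columns are dropped with a logged count.  ``snps`` may be a frame with
    at least ``snp_id`` (missing metadata columns are filled) or a list of
    SNP ids.
    """
    dosage = np.asarray(dosage, dtype=float)
    if dosage.ndim != 2:
        raise ValueError("dosage must be a subjects x SNPs matrix")
    n, m = dosage.shape
    if isinstance(snps, pd.DataFrame):
        meta = snps.reset_index(drop=True).copy()
    else:
        meta = pd.DataFrame({"snp_id": list(snps)})
    if len(meta) != m:
        raise ValueError("snp metadata does not match dosage columns")
    for col, default in (("chrom", "1"), ("pos", 0), ("gene", "")):
        if col not in meta.columns:
            meta[col] = default if col != "pos" else np.arange(1, m + 1)
    if subjects is None:
        subjects = np.array([f"S{i:05d}" for i in range(n)])

    cols, mafs, keep = [], [], []
    for j in range(m):
        g, maf = fold_and_maf(dosage[:, j])
        if g is None:
            continue
        cols.append(g)
        mafs.append(maf)
        keep.append(j)
    n_dropped = m - len(keep)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} monomorphic SNPs", stacklevel=2)
    if not keep:
        genotypes = np.empty((n, 0), dtype=np.int8)
    else:
        genotypes = np.column_stack(cols)
    meta = meta.iloc[keep].reset_index(drop=True)
    meta["maf"] = mafs
    return GenotypePanel(genotypes=genotypes, snps=meta, subjects=np.asarray(subjects))


# ----------------------------------------------------------------------
# Gene-level similarity and distances
# ----------------------------------------------------------------------

def gene_similarity(panel: GenotypePanel, gene: str) -> SimilarityMatrix:
    """Sum of per-SNP scores over the gene's retained SNPs, all pairs.

    Raises :class:`ValueError` for a gene with no retained SNPs (the
    screening driver catches this and skips the gene with a warning).
    """
    idx = panel.gene_map.get(gene)
    if idx is None or len(idx) == 0:
        raise ValueError(f"gene {gene!r} has no retained SNPs")
    G = panel.genotypes[:, idx].astype(np.intp)
    mafs = panel.maf[idx]
    n, m = G.shape
    # sim = sum_k H_k T_k H_k^T computed as one BLAS product:
    #   rowsel[:, 3k:3k+3] = T_k[G[:, k]]   (n x 3 per SNP)
    #   onehot[:, 3k + G[:, k]] = 1
    rowsel = np.empty((n, 3 * m))
    onehot = np.zeros((n, 3 * m))
    rows = np.arange(n)
    for k in range(m):
        t = snp_score_table(mafs[k])
        rowsel[:, 3 * k:3 * k + 3] = t[G[:, k]]
        onehot[rows, 3 * k + G[:, k]] = 1.0
    values = rowsel @ onehot.T
    values = np.triu(values) + np.triu(values, 1).T  # force exact symmetry
    return SimilarityMatrix(gene=gene, values=values, n_snps_used=m)


def similarity_to_distance(S: SimilarityMatrix, *, transform: str = "linear",
                           lam: float = 1.0) -> DistanceMatrix:
    """Turn similarities into distances.

    ``linear`` (default): d(i,j) = max_{m!=n} sim(m,n) - sim(i,j), so the
    most similar pair sits at distance exactly 0.  ``exponential``:
    d = exp(-lam * sim), an optional bounded monotone-decreasing
    alternative.  The diagonal is 0 by definition either way.
    """
    v = S.values
    n = v.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects for distances")
    off = ~np.eye(n, dtype=bool)
    if transform == "linear":
        d = np.where(off, v[off].max() - v, 0.0)
    elif transform == "exponential":
        if lam <= 0:
            raise ValueError("lam must be positive")
        d = np.where(off, np.exp(-lam * v), 0.0)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    d = np.maximum(d, 0.0)  # guard float dust at the max pair
    return DistanceMatrix(values=d)


def filter_snps_by_maf(panel: GenotypePanel, lo: float, hi: float) -> GenotypePanel:
    """Retain SNPs with lo <= observed MAF <= hi (closed interval).

    The "rare window" the screening defaults to is [0.01, 0.05].  An empty
    result is permitted; downstream genes are then skipped.
    """
    if not (0.0 <= lo < hi <= 0.5):
        raise ValueError("need 0 <= lo < hi <= 0.5")
    maf = panel.maf
    keep = np.flatnonzero((maf >= lo) & (maf <= hi))
    out = panel.take_snps(keep)
    # preserve an explicit (possibly overlapping) gene map, reindexed
    if panel._gene_map is not None:
        old_to_new = {int(o): i for i, o in enumerate(keep)}
        out.set_gene_map({
            g: np.asarray([old_to_new[int(j)] for j in ix if int(j) in old_to_new],
                          dtype=int)
            for g, ix in panel._gene_map.items()
        })
    return out
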
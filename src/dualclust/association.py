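"""Association between the phenotype split and per-gene genotype partitions.

The phenotype-side 2-group cluster label is the outcome Y; each gene's
genotype partition is the grouping.  Two scores are computed:

* the partition-retention statistic
  I = sum_i n_i (Ybar_i - Ybar)^2 / (s^2 / n_i)
    = sum_i n_i^2 (Ybar_i - Ybar)^2 / s^2,
  with n_i the size of group i, Ybar_i its mean of Y, and Ybar, s the
  overall mean and (population, denominator n) standard deviation;
* the classical one-way ANOVA F with its asymptotic p-value.

Permutation p-values (permute Y over subjects) are available for both,
plus Bonferroni/Benjamini-Hochberg multiplicity control and a
whole-panel screening driver.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .clustering import Partition, cluster_genotypes, cluster_phenotypes
from .panels import GenotypePanel, TraitPanel, intersect_subjects
from .phenotype import adjust_covariates
from .similarity import filter_snps_by_maf, gene_similarity, similarity_to_distance

__all__ = ["pr_i", "anova_oneway", "permutation_p", "adjust_multiplicity",
           "screen"]


def _group_matrix(part: Partition) -> tuple[np.ndarray, np.ndarray]:
    """One-hot n x k indicator and group sizes for a partition."""
    n = len(part.labels)
    M = np.zeros((n, part.k))
    M[np.arange(n), part.labels - 1] = 1.0
    return M, M.sum(axis=0)


def pr_i(Y, part: Partition, *, normalize_by_n: bool = False) -> float:
    """Partition-retention I of outcome Y against a partition.

    Invariant under affine maps of Y; requires non-constant Y.  The
    ``normalize_by_n`` flag divides by n (an alternative reading that
    rescales by a constant and changes no ranking or permutation p).
    """
    y = np.asarray(Y, dtype=float)
    s2 = y.var()  # population variance, denominator n
    if s2 <= 0:
        raise ValueError("Y is constant; I is undefined (s = 0)")
    ybar = y.mean()
    total = 0.0
    for g in range(1, part.k + 1):
        yg = y[part.labels == g]
        total += len(yg) ** 2 * (yg.mean() - ybar) ** 2
    val = total / s2
    return val / len(y) if normalize_by_n else val


def anova_oneway(Y, part: Partition) -> tuple[float, float]:
    """One-way ANOVA of Y across the partition's groups.

    Returns (F, asymptotic p) with F = (SSB/(k-1)) / (SSW/(n-k)).  A
    zero within-group sum of squares (perfect separation) yields
    F = inf and the smallest positive p, with a warning.
    """
    y = np.asarray(Y, dtype=float)
    n, k = len(y), part.k
    if n <= k:
        raise ValueError("need n > k for one-way ANOVA")
    ybar = y.mean()
    ssb = 0.0
    sst = float(((y - ybar) ** 2).sum())
    for g in range(1, k + 1):
        yg = y[part.labels == g]
        ssb += len(yg) * (yg.mean() - ybar) ** 2
    ssw = sst - ssb
    if ssw <= 1e-12 * max(sst, 1.0):
        warnings.warn("zero within-group variance; F degenerate", stacklevel=2)
        return float("inf"), float(np.finfo(float).tiny)
    f = (ssb / (k - 1)) / (ssw / (n - k))
    p = float(stats.f.sf(f, k - 1, n - k))
    return float(f), max(p, np.finfo(float).tiny)


# ----------------------------------------------------------------------
# Permutation machinery (vectorized over the B permutations)
# ----------------------------------------------------------------------

def _perm_group_sums(y: np.ndarray, M: np.ndarray, B: int,
                     rng: np.random.Generator) -> np.ndarray:
    """B x k matrix of per-group sums of Y under random permutations."""
    perms = rng.permuted(np.tile(y, (B, 1)), axis=1)
    return perms @ M


def _pr_from_sums(S: np.ndarray, sizes: np.ndarray, ybar: float,
                  s2: float) -> np.ndarray:
    # n_i^2 (m_i - ybar)^2 = (S_i - n_i ybar)^2
    return ((S - sizes * ybar) ** 2).sum(axis=-1) / s2


def _f_from_sums(S: np.ndarray, sizes: np.ndarray, ybar: float, sst: float,
                 n: int, k: int) -> np.ndarray:
    ssb = ((S - sizes * ybar) ** 2 / sizes).sum(axis=-1)
    ssw = np.maximum(sst - ssb, 0.0)
    with np.errstate(divide="ignore"):
        return (ssb / (k - 1)) / (ssw / (n - k))


def permutation_p(Y, part: Partition, *, stat: str = "pr", B: int = 10_000,
                  seed=None, **stat_kwargs) -> float:
    """Permutation p-value of a partition statistic.

    ``stat`` is ``"pr"`` (partition-retention I), ``"anova"`` (one-way F)
    or any callable ``f(Y, part)``; Y is permuted over subjects B times
    and p = (1 + #{permuted >= observed}) / (B + 1), so p >= 1/(B+1).
    """
    if B < 100:
        raise ValueError("need B >= 100 permutations")
    y = np.asarray(Y, dtype=float)
    rng = np.random.default_rng(seed)
    if callable(stat):
        obs = stat(y, part, **stat_kwargs)
        count = 0
        for _ in range(B):
            if stat(rng.permutation(y), part, **stat_kwargs) >= obs:
                count += 1
        return (1 + count) / (B + 1)

    M, sizes = _group_matrix(part)
    n, k = len(y), part.k
    ybar, s2, sst = y.mean(), y.var(), float(((y - y.mean()) ** 2).sum())
    S = _perm_group_sums(y, M, B, rng)
    if stat == "pr":
        obs = pr_i(y, part)
        null = _pr_from_sums(S, sizes, ybar, s2)
    elif stat == "anova":
        obs = anova_oneway(y, part)[0]
        null = _f_from_sums(S, sizes, ybar, sst, n, k)
    else:
        raise ValueError(f"unknown statistic {stat!r}")
    return float((1 + np.count_nonzero(null >= obs)) / (B + 1))


def adjust_multiplicity(pvals, method: str = "bonferroni",
                        alpha: float = 0.05):
    """Family-wise (Bonferroni) or FDR (Benjamini-Hochberg) control.

    Returns ``(significant, adjusted)`` boolean/float arrays aligned with
    the input; empty input gives empty output.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must be finite in (0, 1]")
    key = {"bonferroni": "bonferroni", "BH": "fdr_bh", "bh": "fdr_bh"}.get(method)
    if key is None:
        raise ValueError(f"unknown method {method!r}")
    reject, adj, _, _ = multipletests(p, alpha=alpha, method=key)
    return reject, adj


# ----------------------------------------------------------------------
# Screening driver
# ----------------------------------------------------------------------

def screen(panel: GenotypePanel, traits: TraitPanel, *,
           maf_window: tuple[float, float] = (0.01, 0.05),
           k: int = 10, permutations: int = 0, include_skat: bool = False,
           seed=None, multiplicity: str = "bonferroni", alpha: float = 0.05,
           phenotype_partition: Partition | None = None,
           distance_transform: str = "linear") -> pd.DataFrame:
    """Whole-panel gene-by-gene dual-clustering screen.

    Per gene: restrict to SNPs in the MAF window, sum the inverse-
    probability similarity over the gene, convert to distances, Ward-
    cluster into ``k`` groups, and score the partition against the
    phenotype 2-group label with PR's I and one-way ANOVA (optionally a
    permutation p with ``permutations`` draws and a SKAT-like comparator
    p).  Genes with no retained SNPs are skipped with a warning.  Returns
    a frame sorted by p-value with multiplicity-adjusted values attached.
    """
    gi, ti = intersect_subjects(panel, traits)
    if len(gi) < panel.n_subjects or len(ti) < traits.n_subjects:
        panel = panel.take_subjects(gi)
        traits = traits.take_subjects(ti)

    if phenotype_partition is None:
        if traits.adjusted is None:
            traits = adjust_covariates(traits)
        phenotype_partition = cluster_phenotypes(traits)
    y = (phenotype_partition.labels == phenotype_partition.high_group
         ).astype(float) if phenotype_partition.group_means else \
        (phenotype_partition.labels == 1).astype(float)

    genes_all = list(panel.gene_map)  # before filtering, to report skips
    panel = filter_snps_by_maf(panel, *maf_window)
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    gene_seeds = ss.spawn(len(genes_all))

    rows = []
    skipped = []
    for gidx, gene in enumerate(genes_all):
        idx = panel.gene_map.get(gene)
        if idx is None or len(idx) == 0:
            skipped.append(gene)
            continue
        sim = gene_similarity(panel, gene)
        dist = similarity_to_distance(sim, transform=distance_transform)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # k outside [5,10] flagged once upstream
            part = cluster_genotypes(dist, k=k)
        i_score = pr_i(y, part)
        f_stat, p_anova = anova_oneway(y, part)
        p_perm = np.nan
        if permutations:
            p_perm = permutation_p(y, part, stat="pr", B=permutations,
                                   seed=gene_seeds[gidx])
        p_skat = np.nan
        if include_skat:
            from . import skat as _skat
            try:
                w = _skat.skat_weights(panel.maf[idx])
                kern = _skat.skat_kernel(panel.genotypes[:, idx], w, gene=gene)
                p_skat = _skat.skat_test(y, None, kern,
                                         seed=gene_seeds[gidx]).p
            except Exception as exc:  # never silently drop a gene
                warnings.warn(f"SKAT comparator failed for {gene}: {exc}",
                              stacklevel=2)
        rows.append({"gene": gene, "n_snps": int(len(idx)), "k_used": k,
                     "i_score": i_score, "f_stat": f_stat,
                     "p_anova": p_anova, "p_perm": p_perm, "p_skat": p_skat})
    if skipped:
        warnings.warn(f"skipped {len(skipped)} genes with no SNPs in the "
                      f"MAF window {maf_window}", stacklevel=2)
    if not rows:
        return pd.DataFrame(columns=["gene", "n_snps", "k_used", "i_score",
                                     "f_stat", "p_anova", "p_perm", "p_skat",
                                     "p_adj", "significant"])
    out = pd.DataFrame(rows)
    p_primary = out["p_perm"].where(out["p_perm"].notna(), out["p_anova"])
    sig, adj = adjust_multiplicity(p_primary.to_numpy(), method=multiplicity,
                                   alpha=alpha)
    out["p_adj"] = adj
    out["significant"] = sig
    out = out.sort_values("p_anova" if not permutations else "p_perm",
                          kind="mergesort").reset_index(drop=True)
    return out
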
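"""Core in-memory containers shared across the pipeline.

A :class:`GenotypePanel` holds minor-allele genotype counts for a cohort
together with per-SNP metadata (position, gene assignment, observed minor
allele frequency).  A :class:`TraitPanel` holds a longitudinal trait (one
value per subject per exam) together with the covariates used for
adjustment.  Both are thin dataclasses around numpy arrays and pandas
frames; the heavy lifting lives in the sibling modules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["GenotypePanel", "TraitPanel"]

#: columns every SNP metadata frame carries
SNP_COLUMNS = ("snp_id", "chrom", "pos", "gene", "maf")


@dataclass
class GenotypePanel:
    """Subjects x SNPs matrix of minor-allele counts plus SNP metadata.

    Parameters
    ----------
    genotypes:
        ``(n_subjects, n_snps)`` integer array with values in {0, 1, 2},
        already folded so that each column counts the *minor* allele.
    snps:
        Frame with columns ``snp_id, chrom, pos, gene, maf`` (1-based
        positions; ``maf`` is the observed minor allele frequency in
        ``(0, 0.5]``).  Extra columns (e.g. a true simulated MAF) are
        carried along untouched.
    subjects:
        Array of subject identifiers, one per row of ``genotypes``.
    """

    genotypes: np.ndarray
    snps: pd.DataFrame
    subjects: np.ndarray
    _gene_map: dict[str, np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        self.subjects = np.asarray(self.subjects)
        n, m = self.genotypes.shape
        if len(self.subjects) != n:
            raise ValueError("subjects length does not match genotype rows")
        if len(self.snps) != m:
            raise ValueError("snps frame does not match genotype columns")
        missing = [c for c in SNP_COLUMNS if c not in self.snps.columns]
        if missing:
            raise ValueError(f"snps frame missing columns: {missing}")
        if self.genotypes.size:
            gmin, gmax = self.genotypes.min(), self.genotypes.max()
            if gmin < 0 or gmax > 2:
                raise ValueError("genotype values must lie in [0, 2]")
        maf = np.asarray(self.snps["maf"], dtype=float)
        if maf.size and (np.any(maf <= 0) or np.any(maf > 0.5)):
            raise ValueError("observed MAF must lie in (0, 0.5]; "
                             "monomorphic SNPs must be filtered at load")

    # ------------------------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def maf(self) -> np.ndarray:
        return np.asarray(self.snps["maf"], dtype=float)

    @property
    def gene_map(self) -> Mapping[str, np.ndarray]:
        """Mapping gene label -> SNP column indices.

        Built from the ``gene`` metadata column unless an explicit
        (possibly overlapping) map was attached with :meth:`set_gene_map`.
        SNPs with a missing/empty gene label are excluded from all
        gene-level analyses.
        """
        if self._gene_map is None:
            gm: dict[str, list[int]] = {}
            for j, g in enumerate(self.snps["gene"]):
                if g is None or (isinstance(g, float) and np.isnan(g)) or g == "":
                    continue
                gm.setdefault(str(g), []).append(j)
            self._gene_map = {g: np.asarray(ix, dtype=int) for g, ix in gm.items()}
        return self._gene_map

    def set_gene_map(self, mapping: Mapping[str, np.ndarray]) -> None:
        """Attach an explicit gene->SNP-column map (genes may overlap)."""
        self._gene_map = {g: np.asarray(ix, dtype=int) for g, ix in mapping.items()}

    @property
    def genes(self) -> list[str]:
        return list(self.gene_map)

    # ------------------------------------------------------------------
    def take_snps(self, index: np.ndarray) -> "GenotypePanel":
        """Panel restricted to the given SNP column indices (order kept)."""
        index = np.asarray(index, dtype=int)
        return GenotypePanel(
            genotypes=self.genotypes[:, index],
            snps=self.snps.iloc[index].reset_index(drop=True),
            subjects=self.subjects,
        )

    def take_subjects(self, index: np.ndarray, *, refold: bool = True) -> "GenotypePanel":
        """Panel restricted to the given subject row indices.

        Observed MAFs refer to the analyzed cohort, so by default columns
        are re-folded and newly monomorphic SNPs dropped (``refold=True``).
        """
        index = np.asarray(index, dtype=int)
        sub = self.genotypes[index]
        if not refold:
            return GenotypePanel(sub, self.snps.copy(), self.subjects[index])
        from .similarity import panel_from_dosage  # local import: avoids cycle

        return panel_from_dosage(sub, self.snps, self.subjects[index])

    @classmethod
    def from_dosage(cls, dosage, snps, subjects=None) -> "GenotypePanel":
        """Round dosages to genotypes, fold to the minor allele, drop
        monomorphic columns; see :func:`dualclust.similarity.panel_from_dosage`."""
        from .similarity import panel_from_dosage

        return panel_from_dosage(dosage, snps, subjects)


@dataclass
class TraitPanel:
    """One longitudinal trait: subjects x time-points values plus covariates.

    ``raw`` holds the measured trait (e.g. SBP in mmHg), ``adjusted`` the
    per-exam OLS residuals produced by
    :func:`dualclust.phenotype.adjust_covariates` (``None`` until then).
    ``covariates`` must contain ``age`` (years) and ``sex`` (0/1) plus
    either a single ``medication`` column or per-exam ``med_t0..``
    columns (0/1 antihypertensive-use indicator).
    """

    subjects: np.ndarray
    raw: np.ndarray
    covariates: pd.DataFrame
    adjusted: np.ndarray | None = None
    trait_name: str = "trait"
    replicate: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.subjects = np.asarray(self.subjects)
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.ndim != 2:
            raise ValueError("raw trait matrix must be subjects x time-points")
        if len(self.subjects) != self.raw.shape[0]:
            raise ValueError("subjects length does not match trait rows")
        if len(self.covariates) != self.raw.shape[0]:
            raise ValueError("covariate rows do not match trait rows")
        if self.adjusted is not None:
            self.adjusted = np.asarray(self.adjusted, dtype=float)
            if self.adjusted.shape != self.raw.shape:
                raise ValueError("adjusted and raw must have the same shape")

    @property
    def n_subjects(self) -> int:
        return self.raw.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.raw.shape[1]

    def medication_at(self, t: int) -> np.ndarray:
        """Medication indicator at exam ``t`` (per-exam column if present,
        else the constant ``medication`` column)."""
        col = f"med_t{t}"
        if col in self.covariates.columns:
            return np.asarray(self.covariates[col], dtype=float)
        if "medication" in self.covariates.columns:
            return np.asarray(self.covariates["medication"], dtype=float)
        raise KeyError("no medication covariate found")

    def take_subjects(self, index: np.ndarray) -> "TraitPanel":
        index = np.asarray(index, dtype=int)
        return replace(
            self,
            subjects=self.subjects[index],
            raw=self.raw[index],
            covariates=self.covariates.iloc[index].reset_index(drop=True),
            adjusted=None if self.adjusted is None else self.adjusted[index],
        )


def intersect_subjects(panel: GenotypePanel, traits: TraitPanel):
    """Indices aligning a genotype panel and a trait panel on subject id.

    Returns ``(geno_idx, trait_idx)`` such that
    ``panel.subjects[geno_idx] == traits.subjects[trait_idx]``, in the
    genotype panel's order.  Dropped subjects are reported with a warning;
    an empty intersection is fatal.
    """
    tpos = {s: i for i, s in enumerate(traits.subjects)}
    gi, ti = [], []
    for i, s in enumerate(panel.subjects):
        j = tpos.get(s)
        if j is not None:
            gi.append(i)
            ti.append(j)
    if not gi:
        raise ValueError("genotype and phenotype subject sets are disjoint")
    n_drop_g = panel.n_subjects - len(gi)
    n_drop_t = traits.n_subjects - len(ti)
    if n_drop_g or n_drop_t:
        warnings.warn(
            f"subject intersection dropped {n_drop_g} genotype-only and "
            f"{n_drop_t} phenotype-only subjects", stacklevel=2)
    return np.asarray(gi, dtype=int), np.asarray(ti, dtype=int)
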
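"""Synthetic genotype panels and longitudinal traits.

Emulates the structure of a whole-genome-sequencing cohort with simulated
longitudinal blood-pressure-like traits: unrelated subjects, Hardy-
Weinberg genotypes with a rare-variant-rich MAF spectrum, contiguous
genes of tens of SNPs, and a trait measured at a few exams with
covariate effects plus an optional gene-level genetic effect that may be
constant in time (``level``), grow with the exam index (``slope``) or
flip sign across exams (``crossing``).

All randomness flows from ``SimConfig.seed`` through named child
streams, so identical configs give bit-identical output and any single
replicate is regenerable in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .panels import GenotypePanel, TraitPanel
from .similarity import panel_from_dosage

__all__ = ["SimConfig", "simulate_genotypes", "simulate_traits",
           "simulate_replicates", "causal_snp_indices"]

_EFFECT_MODELS = ("level", "slope", "crossing")

#: named substreams of the master seed
_STREAM_GENOTYPES = 0
_STREAM_COVARIATES = 1
_STREAM_CAUSAL = 2
_STREAM_TRAITS = 1000  # + replicate index


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


@dataclass(frozen=True)
class SimConfig:
    """Stated world for the generator.

    Defaults describe an SBP-like trait in mmHg at 3 exams for unrelated
    subjects: intercept 120, age +0.3/yr, sex +2, antihypertensive
    medication -5, residual noise SD 5.  The MAF law defaults to
    Uniform(0.01, 0.05), the rare window the screening analyses.  A
    causal gene shifts the trait by ``effect_size`` mmHg per minor allele
    carried on its causal SNPs (all SNPs with true MAF < 0.05 by default,
    or a configured fraction of them), per unit of the time profile.
    """

    n_subjects: int = 500
    n_genes: int = 50
    snps_per_gene: int | tuple[int, int] = 20
    maf_law: tuple = ("uniform", 0.01, 0.05)
    n_timepoints: int = 3
    causal_genes: tuple[int, ...] = ()
    effect_model: str = "level"
    effect_size: float = 2.0
    causal_snp_fraction: float = 1.0
    covariate_effects: dict = field(default_factory=lambda: {
        "age": 0.3, "sex": 2.0, "age_sex": 0.0, "medication": -5.0})
    intercept: float = 120.0
    noise_sd: float = 5.0
    trait_name: str = "SBP"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_genes", "n_timepoints"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.snp_range
        if lo <= 0 or hi < lo:
            raise ValueError("snps_per_gene must be a positive count or range")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 < self.causal_snp_fraction <= 1.0:
            raise ValueError("causal_snp_fraction must lie in (0, 1]")
        if self.effect_model not in _EFFECT_MODELS:
            raise ValueError(f"effect_model must be one of {_EFFECT_MODELS}")
        for g in self.causal_genes:
            if not 0 <= g < self.n_genes:
                raise ValueError(f"causal gene index {g} out of range")
        self._check_maf_law()

    @property
    def snp_range(self) -> tuple[int, int]:
        s = self.snps_per_gene
        return (s, s) if isinstance(s, int) else (int(s[0]), int(s[1]))

    def _check_maf_law(self) -> None:
        kind = self.maf_law[0]
        if kind == "uniform":
            _, lo, hi = self.maf_law
            if not (0.0 < lo < hi < 0.5):
                raise ValueError("uniform maf_law support must lie inside (0, 0.5)")
        elif kind == "point":
            _, p = self.maf_law
            if not 0.0 < p < 0.5:
                raise ValueError("point maf_law must lie inside (0, 0.5)")
        elif kind == "beta":
            _, a, b = self.maf_law
            if a <= 0 or b <= 0:
                raise ValueError("beta maf_law shapes must be positive")
        else:
            raise ValueError(f"unknown maf_law kind {kind!r}")

    def sample_mafs(self, rng: np.random.Generator, size: int) -> np.ndarray:
        kind = self.maf_law[0]
        if kind == "uniform":
            return rng.uniform(self.maf_law[1], self.maf_law[2], size=size)
        if kind == "point":
            return np.full(size, float(self.maf_law[1]))
        # beta on (0, 0.5), truncated away from 0 so the law has support
        # strictly inside (0, 0.5)
        draws = 0.5 * rng.beta(self.maf_law[1], self.maf_law[2], size=size)
        return np.clip(draws, 1e-4, 0.5 - 1e-4)

    def time_profile(self) -> np.ndarray:
        """Per-exam multiplier of the genetic effect, exam index t = 0..T-1."""
        t = np.arange(self.n_timepoints, dtype=float)
        if self.effect_model == "level":
            return np.ones_like(t)
        if self.effect_model == "slope":
            return t
        return t - (self.n_timepoints - 1) / 2.0  # crossing: sign flip


# ----------------------------------------------------------------------

def simulate_genotypes(config: SimConfig) -> GenotypePanel:
    """HWE genotypes for unrelated subjects, SNPs contiguous within genes.

    Each SNP's true MAF p is drawn from the configured law and genotypes
    are Binomial(2, p), i.e. Hardy-Weinberg proportions
    ((1-p)^2, 2p(1-p), p^2).  The true MAF is kept in the metadata as
    ``true_maf``; the panel's ``maf`` column is the observed (folded)
    frequency.  SNPs monomorphic in the sample are dropped at folding.
    """
    rng = _rng(config.seed, _STREAM_GENOTYPES)
    lo, hi = config.snp_range
    counts = (np.full(config.n_genes, lo) if lo == hi
              else rng.integers(lo, hi + 1, size=config.n_genes))
    m = int(counts.sum())
    mafs = config.sample_mafs(rng, m)
    dosage = rng.binomial(2, mafs, size=(config.n_subjects, m)).astype(float)

    gene_of = np.repeat([f"gene{g:04d}" for g in range(config.n_genes)], counts)
    snps = pd.DataFrame({
        "snp_id": [f"snp{j:06d}" for j in range(m)],
        "chrom": "1",
        "pos": np.arange(1, m + 1) * 1000,
        "gene": gene_of,
        "true_maf": mafs,
    })
    subjects = np.array([f"S{i:05d}" for i in range(config.n_subjects)])
    return panel_from_dosage(dosage, snps, subjects)


def causal_snp_indices(panel: GenotypePanel, config: SimConfig,
                       gene_index: int) -> np.ndarray:
    """Columns of the causal SNPs of a causal gene.

    Default: every SNP of the gene with true MAF < 0.05 (the rare-variant
    architecture the screen targets); ``causal_snp_fraction`` < 1 keeps a
    deterministic (seeded) subset of that size.
    """
    gene = f"gene{gene_index:04d}"
    idx = panel.gene_map.get(gene)
    if idx is None:
        return np.empty(0, dtype=int)
    maf = (np.asarray(panel.snps["true_maf"], dtype=float)
           if "true_maf" in panel.snps.columns else panel.maf)
    eligible = idx[maf[idx] < 0.05]
    if config.causal_snp_fraction >= 1.0 or len(eligible) == 0:
        return eligible
    n_keep = max(1, int(np.ceil(config.causal_snp_fraction * len(eligible))))
    rng = _rng(config.seed, _STREAM_CAUSAL)
    return np.sort(rng.choice(eligible, size=n_keep, replace=False))


def _covariates(config: SimConfig) -> pd.DataFrame:
    """Age ~ uniform integers 30-80, sex ~ Bernoulli(0.5), medication ~
    Bernoulli(0.3) per exam, mutually independent; fixed across replicates."""
    rng = _rng(config.seed, _STREAM_COVARIATES)
    n, T = config.n_subjects, config.n_timepoints
    cov = {
        "age": rng.integers(30, 81, size=n).astype(float),
        "sex": rng.integers(0, 2, size=n).astype(float),
    }
    for t in range(T):
        cov[f"med_t{t}"] = (rng.random(n) < 0.3).astype(float)
    return pd.DataFrame(cov)


def simulate_traits(panel: GenotypePanel, config: SimConfig,
                    replicate: int = 0) -> TraitPanel:
    """Longitudinal trait for every subject of ``panel``.

    trait(i, t) = intercept + covariate terms
                + sum over causal genes of profile(t) * effect_size * burden(i)
                + Gaussian noise,
    where burden(i) is the subject's minor-allele count on the gene's
    causal SNPs.  Covariates are fixed by the master seed; noise is drawn
    from a replicate-specific stream.
    """
    if panel.n_subjects != config.n_subjects:
        raise ValueError("panel is inconsistent with config (n_subjects)")
    n, T = config.n_subjects, config.n_timepoints
    cov = _covariates(config)
    ce = config.covariate_effects
    profile = config.time_profile()

    genetic = np.zeros(n)
    for g in config.causal_genes:
        cols = causal_snp_indices(panel, config, g)
        if len(cols):
            genetic = genetic + panel.genotypes[:, cols].sum(axis=1)
    genetic = config.effect_size * genetic

    noise_rng = _rng(config.seed, _STREAM_TRAITS + replicate)
    raw = np.empty((n, T))
    for t in range(T):
        raw[:, t] = (config.intercept
                     + ce.get("age", 0.0) * cov["age"].to_numpy()
                     + ce.get("sex", 0.0) * cov["sex"].to_numpy()
                     + ce.get("age_sex", 0.0) * (cov["age"] * cov["sex"]).to_numpy()
                     + ce.get("medication", 0.0) * cov[f"med_t{t}"].to_numpy()
                     + profile[t] * genetic
                     + noise_rng.normal(0.0, config.noise_sd, size=n))
    return TraitPanel(subjects=panel.subjects, raw=raw, covariates=cov,
                      trait_name=config.trait_name, replicate=replicate,
                      seed=int(config.seed))


def simulate_replicates(config: SimConfig, n_replicates: int
                        ) -> tuple[GenotypePanel, list[TraitPanel]]:
    """One genotype panel plus ``n_replicates`` independent trait panels.

    Genotypes are drawn once; only the phenotype noise is re-drawn, from
    per-replicate derived streams, so replicate r is exactly
    ``simulate_traits(panel, config, replicate=r)``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    panel = simulate_genotypes(config)
    reps = [simulate_traits(panel, config, replicate=r)
            for r in range(n_replicates)]
    return panel, reps
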
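"""Readers/writers for the standard formats and the pipeline driver.

Conventions: VCF and SNP-map positions are 1-based; BED gene intervals
are 0-based half-open (a SNP at 1-based position P lies in [start, end)
iff start <= P-1 < end).  A SNP overlapping several gene intervals is
assigned to all of them.  Dosage matrices are plain TSV with subjects as
rows; phenotypes are wide CSV.  All randomness in the pipeline flows
from the configured seed and every filter count is logged, so a run is
fully reproducible from its config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .association import screen
from .clustering import Partition, cluster_phenotypes
from .panels import GenotypePanel, TraitPanel
from .phenotype import adjust_covariates
from .similarity import panel_from_dosage

__all__ = ["RunConfig", "read_genotypes", "write_genotypes", "read_gene_map",
           "read_phenotypes", "write_phenotypes", "run_pipeline"]

log = logging.getLogger("dualclust")


# ----------------------------------------------------------------------
# Genotypes
# ----------------------------------------------------------------------

def _read_vcf(path: str | Path) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - cyvcf2 present in CI env
        raise ImportError("reading VCF requires cyvcf2") from exc
    vcf = VCF(str(path))
    subjects = np.asarray(vcf.samples)
    cols, meta = [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        ds = var.format("DS")
        if ds is not None:
            dose = np.asarray(ds, dtype=float).ravel()
        else:
            # GT fallback: ALT allele count; missing -> NaN
            gts = np.asarray(var.genotype.array())[:, :2]
            dose = np.where((gts < 0).any(axis=1), np.nan,
                            (gts > 0).sum(axis=1)).astype(float)
        cols.append(dose)
        meta.append({"snp_id": var.ID or f"{var.CHROM}:{var.POS}",
                     "chrom": str(var.CHROM), "pos": int(var.POS), "gene": ""})
    if n_multi:
        log.warning("skipped %d multiallelic records", n_multi)
    dosage = np.column_stack(cols) if cols else np.empty((len(subjects), 0))
    return dosage, pd.DataFrame(meta), subjects


def _read_dosage_tsv(path: str | Path) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "subject_id":
        raise ValueError("dosage TSV must start with a subject_id column")
    subjects = df["subject_id"].to_numpy()
    body = df.drop(columns="subject_id")
    mat = body.to_numpy()
    if mat.dtype.kind not in "fi":
        for col in body.columns:
            vals = pd.to_numeric(body[col], errors="coerce")
            rows = body.index[vals.isna() & body[col].notna()]
            if len(rows):
                raise ValueError(
                    f"non-numeric dosage at row {rows[0] + 2}, column {col!r}")
        raise ValueError("non-numeric dosage values in TSV")
    meta = pd.DataFrame({"snp_id": body.columns, "chrom": "1",
                         "pos": np.arange(1, body.shape[1] + 1), "gene": ""})
    return mat.astype(float), meta, subjects


def read_genotypes(path: str | Path, format: str = "tsv",
                   snp_map: str | Path | None = None) -> GenotypePanel:
    """Load a genotype panel from a VCF (DS field, GT fallback) or a
    dosage TSV, folding to minor-allele counts and dropping monomorphic
    SNPs with a logged count.

    ``snp_map`` is a TSV with columns ``snp_id, chrom, pos, gene``; when
    given, it overrides the positional metadata and supplies gene labels.
    """
    if format == "vcf":
        dosage, meta, subjects = _read_vcf(path)
    elif format == "tsv":
        dosage, meta, subjects = _read_dosage_tsv(path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")
    if snp_map is not None:
        sm = pd.read_csv(snp_map, sep="\t", dtype={"snp_id": str, "chrom": str,
                                                   "gene": str})
        sm = sm.set_index("snp_id")
        known = meta["snp_id"].isin(sm.index)
        for colname in ("chrom", "pos", "gene"):
            if colname in sm.columns:
                meta.loc[known, colname] = sm.loc[
                    meta.loc[known, "snp_id"], colname].to_numpy()
    n_before = dosage.shape[1]
    panel = panel_from_dosage(dosage, meta, subjects)
    log.info("loaded %d subjects x %d SNPs (%d monomorphic dropped)",
             panel.n_subjects, panel.n_snps, n_before - panel.n_snps)
    return panel


def write_genotypes(panel: GenotypePanel, prefix: str | Path,
                    format: str = "tsv") -> list[Path]:
    """Write a panel as dosage TSV + SNP-map TSV, or as a plain-text VCF
    with a DS FORMAT field.  Returns the written paths."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if format == "tsv":
        dosage_path = prefix.with_suffix(".dosage.tsv")
        map_path = prefix.with_suffix(".snps.tsv")
        df = pd.DataFrame(panel.genotypes,
                          columns=panel.snps["snp_id"].tolist())
        df.insert(0, "subject_id", panel.subjects)
        df.to_csv(dosage_path, sep="\t", index=False)
        panel.snps[["snp_id", "chrom", "pos", "gene"]].to_csv(
            map_path, sep="\t", index=False)
        return [dosage_path, map_path]
    if format == "vcf":
        vcf_path = prefix.with_suffix(".vcf")
        with open(vcf_path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                     'Description="Minor allele dosage">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(map(str, panel.subjects)) + "\n")
            for j in range(panel.n_snps):
                row = panel.snps.iloc[j]
                ds = "\t".join(f"{g:g}" for g in panel.genotypes[:, j])
                fh.write(f"{row['chrom']}\t{int(row['pos'])}\t{row['snp_id']}"
                         f"\tA\tC\t.\tPASS\t.\tDS\t{ds}\n")
        return [vcf_path]
    raise ValueError(f"unknown genotype format {format!r}")


# ----------------------------------------------------------------------
# Gene maps
# ----------------------------------------------------------------------

def read_gene_map(path: str | Path, format: str = "bed") -> pd.DataFrame:
    """Load gene intervals (BED, 0-based half-open) or an explicit
    snp_id -> gene table.  Returns a frame with either
    (chrom, start, end, gene) or (snp_id, gene) columns."""
    if format == "bed":
        bed = pd.read_csv(path, sep="\t", header=None, comment="#",
                          usecols=[0, 1, 2, 3],
                          names=["chrom", "start", "end", "gene"],
                          dtype={"chrom": str, "gene": str})
        bad = bed["start"] >= bed["end"]
        if bad.any():
            raise ValueError(
                f"BED interval with start >= end at line {int(bad.idxmax()) + 1}")
        return bed
    if format == "table":
        tab = pd.read_csv(path, sep="\t", dtype=str)
        if list(tab.columns[:2]) != ["snp_id", "gene"]:
            tab.columns = ["snp_id", "gene"] + list(tab.columns[2:])
        return tab[["snp_id", "gene"]]
    raise ValueError(f"unknown gene map format {format!r}")


def assign_genes(panel: GenotypePanel, gene_map: pd.DataFrame) -> None:
    """Attach gene assignments to a panel in place.

    BED frames assign a SNP (1-based position P) to every interval with
    start <= P-1 < end, so overlapping genes each receive the SNP; a
    two-column table assigns by snp_id.  Unassigned SNPs are excluded
    from gene-level analyses with a logged count.
    """
    mapping: dict[str, list[int]] = {}
    if {"chrom", "start", "end"}.issubset(gene_map.columns):
        pos0 = np.asarray(panel.snps["pos"], dtype=int) - 1  # BED coordinate
        chrom = panel.snps["chrom"].astype(str).to_numpy()
        for _, row in gene_map.iterrows():
            hit = np.flatnonzero((chrom == str(row["chrom"]))
                                 & (pos0 >= int(row["start"]))
                                 & (pos0 < int(row["end"])))
            if len(hit):
                mapping.setdefault(str(row["gene"]), []).extend(hit.tolist())
    else:
        by_id = {}
        for _, row in gene_map.iterrows():
            by_id.setdefault(str(row["snp_id"]), []).append(str(row["gene"]))
        for j, sid in enumerate(panel.snps["snp_id"].astype(str)):
            for g in by_id.get(sid, ()):
                mapping.setdefault(g, []).append(j)
    assigned = set()
    for ix in mapping.values():
        assigned.update(ix)
    n_un = panel.n_snps - len(assigned)
    if n_un:
        log.info("%d SNPs not assigned to any gene", n_un)
    panel.set_gene_map({g: np.asarray(sorted(set(ix)), dtype=int)
                        for g, ix in mapping.items()})


# ----------------------------------------------------------------------
# Phenotypes
# ----------------------------------------------------------------------

def read_phenotypes(path: str | Path, trait_name: str = "trait") -> TraitPanel:
    """Wide phenotype CSV: subject_id, age, sex, med_t0.., trait_t0.. ."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    need = {"subject_id", "age", "sex"}
    if not need.issubset(df.columns):
        raise ValueError(f"phenotype CSV must contain columns {sorted(need)}")
    trait_cols = sorted([c for c in df.columns if c.startswith("trait_t")],
                        key=lambda c: int(c.split("trait_t")[1]))
    if not trait_cols:
        raise ValueError("phenotype CSV has no trait_t* columns")
    med_cols = [c for c in df.columns if c.startswith("med_t")] \
        + (["medication"] if "medication" in df.columns else [])
    cov = df[["age", "sex"] + med_cols].astype(float).reset_index(drop=True)
    return TraitPanel(subjects=df["subject_id"].to_numpy(),
                      raw=df[trait_cols].to_numpy(dtype=float),
                      covariates=cov, trait_name=trait_name)


def write_phenotypes(traits: TraitPanel, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = pd.DataFrame({"subject_id": traits.subjects})
    for c in traits.covariates.columns:
        out[c] = traits.covariates[c].to_numpy()
    for t in range(traits.n_timepoints):
        out[f"trait_t{t}"] = traits.raw[:, t]
    out.to_csv(path, index=False)
    return path


def write_partition(part: Partition, subjects: np.ndarray,
                    path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"subject_id": subjects, "group": part.labels}).to_csv(
        path, sep="\t", index=False)
    return path


# ----------------------------------------------------------------------
# Pipeline
# ----------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of a full screening run (YAML-serializable)."""

    genotypes: str = ""
    genotype_format: str = "tsv"
    snp_map: str | None = None
    gene_map: str | None = None
    gene_map_format: str = "bed"
    phenotypes: str = ""
    trait_name: str = "trait"
    maf_lo: float = 0.01
    maf_hi: float = 0.05
    k_genotype: int = 10
    k_phenotype: int = 2
    permutations: int = 0
    include_skat: bool = False
    multiplicity: str = "bonferroni"
    alpha: float = 0.05
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_lo < self.maf_hi <= 0.5:
            raise ValueError("need 0 <= maf_lo < maf_hi <= 0.5")
        if self.k_genotype < 2:
            raise ValueError("k_genotype must be >= 2")
        if self.k_phenotype != 2:
            raise ValueError("the phenotype tree is cut into 2 groups")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """read -> adjust -> phenotype clustering -> per-gene screen -> report.

    Writes ``results.tsv`` (sorted by p), ``phenotype_partition.tsv`` and
    ``run_config.yaml`` under ``config.out_dir`` and returns the result
    frame.  Identical config + seed give byte-identical outputs.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    panel = read_genotypes(config.genotypes, format=config.genotype_format,
                           snp_map=config.snp_map)
    if config.gene_map:
        assign_genes(panel, read_gene_map(config.gene_map,
                                          format=config.gene_map_format))
    traits = read_phenotypes(config.phenotypes, trait_name=config.trait_name)

    traits = adjust_covariates(traits)
    results = screen(panel, traits,
                     maf_window=(config.maf_lo, config.maf_hi),
                     k=config.k_genotype,
                     permutations=config.permutations,
                     include_skat=config.include_skat,
                     seed=config.seed,
                     multiplicity=config.multiplicity,
                     alpha=config.alpha)
    results.to_csv(out_dir / "results.tsv", sep="\t", index=False,
                   float_format="%.10g")
    # phenotype partition on the intersected cohort, for the record
    from .panels import intersect_subjects
    gi, ti = intersect_subjects(panel, traits)
    tsub = adjust_covariates(traits.take_subjects(ti))
    part = cluster_phenotypes(tsub)
    write_partition(part, tsub.subjects, out_dir / "phenotype_partition.tsv")
    config.to_yaml(out_dir / "run_config.yaml")
    log.info("screen finished: %d genes scored, %d significant at %s alpha=%g",
             len(results), int(results["significant"].sum()) if len(results) else 0,
             config.multiplicity, config.alpha)
    return results
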
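import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make helpers importable

from dualclust import GenotypePanel, SimConfig, simulate_genotypes


@pytest.fixture
def rng():
    return np.random.default_rng(20240301)


@pytest.fixture(scope="session")
def toy_panel() -> GenotypePanel:
    """Tiny hand-checkable panel: 6 subjects, 2 genes of 2 SNPs."""
    genotypes = np.array([
        [0, 1, 0, 2],
        [1, 0, 0, 1],
        [2, 1, 1, 0],
        [0, 0, 2, 0],
        [1, 2, 0, 1],
        [0, 0, 1, 0],
    ], dtype=np.int8)
    n = genotypes.shape[0]
    maf = genotypes.sum(axis=0) / (2 * n)
    snps = pd.DataFrame({
        "snp_id": [f"rs{i}" for i in range(4)],
        "chrom": "1",
        "pos": [100, 200, 300, 400],
        "gene": ["GA", "GA", "GB", "GB"],
        "maf": maf,
    })
    subjects = np.array([f"S{i}" for i in range(n)])
    return GenotypePanel(genotypes=genotypes, snps=snps, subjects=subjects)


@pytest.fixture(scope="session")
def sim_panel() -> GenotypePanel:
    """Moderate synthetic panel shared by read-only tests."""
    cfg = SimConfig(n_subjects=150, n_genes=6, snps_per_gene=10, seed=11)
    return simulate_genotypes(cfg)
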
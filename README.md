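# dualclust

Gene-based association screening between whole-genome-sequencing
genotypes and **longitudinal** traits, built around a dual-clustering
idea: partition the cohort twice — once from genotypes, once from
phenotype trajectories — and score how strongly the two partitions
agree, gene by gene.

Rare variants (MAF < 5%) carry most of the interesting signal in
sequencing studies but defeat single-marker tests.  `dualclust`
aggregates them with an inverse-probability-weighted similarity: for
SNP *k* with observed minor allele frequency *p_k* and minor-allele
counts *g_ik*, the pairwise score sim(i, j; k) is large when two
subjects share a rare allele (the (1,1) case behaves like 1/p_k² as
p_k → 0), near zero when they share only the common homozygote, and
negative (−1/(p_k(1−p_k))) when their homozygotes disagree.  Gene-level
similarity is the sum over the gene's SNPs, turned into a distance
d(i,j) = max sim − sim(i,j) and fed to Ward hierarchical clustering
(k = 5–10 groups, default 10).  Independently, each subject's trait
trajectory (e.g. blood pressure at 3 exams, residualized on age, sex,
age×sex and medication) is Ward-clustered into 2 groups — high vs low.

Association between the 2-group phenotype label Y and a gene's
partition Π is scored with the partition-retention statistic

    I = Σ_i n_i (Ȳ_i − Ȳ)² / (s²/n_i)

and classical one-way ANOVA, with permutation p-values and
Bonferroni/Benjamini–Hochberg control.  A SKAT-style linear
weighted-kernel score test (Q = r'Kr, K = G·diag(w)·G', Beta(1,25)²
weights) is included as the comparator, and an ROC/AUC harness (with
paired Wilcoxon signed-rank AUC comparison across simulation
replicates) evaluates methods against a known causal-gene truth set.
A synthetic-data module generates Hardy–Weinberg genotype panels and
longitudinal traits with configurable gene effects (constant, growing
with exam index, or sign-flipping across exams), so every stage is
testable without access-restricted cohort data.

## Worked example

```python
import dualclust as dc

cfg = dc.SimConfig(n_subjects=300, n_genes=8, snps_per_gene=12,
                   causal_genes=(2,), effect_model="slope", seed=31)
panel = dc.simulate_genotypes(cfg)
traits = dc.adjust_covariates(dc.simulate_traits(panel, cfg))
res = dc.screen(panel, traits, maf_window=(0.0, 0.5), k=10, seed=0)
print(res[["gene", "n_snps", "i_score", "f_stat", "p_anova", "significant"]]
      .head(3).to_string(index=False))
```

prints

```
    gene  n_snps     i_score   f_stat  p_anova  significant
gene0002      12 2239.107069 4.303226 0.000029         True
gene0006      12  690.963208 1.605394 0.113070        False
gene0007      12  143.460934 1.193552 0.298695        False
```

The causal gene (`gene0002`, whose rare-variant burden tilts the trait
trajectory upward across exams) tops the screen with I ≈ 2239 and an
ANOVA p ≈ 3·10⁻⁵ that survives Bonferroni correction over the 8 genes;
the runner-up null genes have unremarkable p-values.

The same pipeline is available from the shell:

```sh
dualclust simulate --n-subjects 300 --n-genes 8 --causal-genes 2 \
    --effect-model slope --seed 31 --out sim/
dualclust screen --genotypes sim/genotypes.dosage.tsv \
    --snp-map sim/genotypes.snps.tsv --phenotypes sim/phenotypes_rep000.csv \
    --perm 2000 --skat --seed 0 --out results/
dualclust evaluate --results results/results.tsv \
    --truth sim/causal_genes.txt --methods pr,anova,skat --out eval/
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates a synthetic cohort from the given seed, runs the full
screen (PR, ANOVA and the SKAT-like comparator, with permutation
p-values) on ten phenotype replicates, prints the replicate-averaged
AUC of each method and the paired Wilcoxon comparison, and writes the
results JSON to `--out`.
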
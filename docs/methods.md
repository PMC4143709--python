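# Methods

## The screening model

`dualclust` tests, gene by gene, whether the genotypic structure of a
cohort is associated with the shape of a longitudinal trait.  Both
sides of the association are reduced to partitions of the subjects
before any testing happens:

1. **Genotype side (one partition per gene).**  For SNP *k* with
   observed minor allele frequency *p_k* and minor-allele counts
   *g_ik* ∈ {0, 1, 2}, the pairwise similarity sim(i, j; k) is a
   function of the unordered genotype pair only:

   | pair | score |
   |---|---|
   | (0,0) | 2p² |
   | (1,1) | ½(1/p² + 1/(1−p)²) − 1/(p(1−p)) |
   | (2,2) | 2(1−p)² |
   | (0,1) | 1/(1−p)² − ½·1/(p(1−p)) |
   | (0,2) | −1/(p(1−p)) |
   | (1,2) | 1/p² − ½·1/(p(1−p)) |

   The weighting is *inverse-probability* in spirit: sharing the rare
   allele scores roughly like the reciprocal of the sharing
   probability, so rare matches dominate, matches on the common
   homozygote contribute almost nothing, and discordant homozygotes
   repel.  Gene similarity is the sum over the gene's retained SNPs;
   distances are d(i,j) = max_{m≠n} sim(m,n) − sim(i,j) (the most
   similar pair at distance exactly 0; an exponential transform
   d = exp(−λ·sim) is available behind a flag).  Ward hierarchical
   clustering of these distances, cut into k groups (5–10 studied,
   default 10), gives the gene's partition.

   The coefficient table lives in a single function
   (`similarity._score_cases`) and is evaluated in exact rational
   arithmetic on the exact binary value of p, rounded to float once.
   That makes the table bit-reproducible, auditable (changing one
   coefficient is a one-line change the whole suite re-verifies) and
   exactly comparable to the symbolic oracle in the tests.  One
   property of this table worth knowing: for small p the (1,1) score
   exceeds the (2,2) score, i.e. heterozygous sharing of a rare allele
   outranks rare-homozygote sharing.  It is preserved as transcribed;
   only the magnitudes, not the orderings used downstream, would
   change under the alternative reading.

2. **Phenotype side (one partition per trait replicate).**  The trait
   at each exam is residualized by OLS on intercept, age, sex,
   age×sex and the exam's medication indicator (cross-sectional per
   exam — no joint longitudinal model, which is the minimal reading of
   residualize-then-cluster).  The T-dimensional residual trajectories
   are Ward-clustered on Euclidean distances and cut into 2 groups,
   interpretable as high vs low trait; the group with the larger mean
   trajectory is labelled "high".

Association between the binary phenotype label Y and a gene's
partition Π (groups i = 1..k of sizes n_i) is scored with

* **partition retention**: I = Σ_i n_i (Ȳ_i − Ȳ)²/(s²/n_i)
  = Σ_i n_i²(Ȳ_i − Ȳ)²/s², with s the population (denominator-n)
  standard deviation of Y.  I is affine-invariant in Y and grows with
  both group separation and group size.  An alternative normalization
  dividing by n exists in the literature; for fixed n it rescales by a
  constant and changes no ranking, permutation p or ROC curve, so it
  is exposed only as a flag (`normalize_by_n`).
* **one-way ANOVA**: F = (SSB/(k−1))/(SSW/(n−k)) with the asymptotic
  F(k−1, n−k) p-value.

Permutation p-values (permute Y over subjects; p = (1 + #{≥ obs})/(B+1),
B default 10,000) are recommended for inference because the cohort
structure (relatedness in real data, degenerate partitions) can
inflate asymptotic p-values; family-wise (Bonferroni, default) and FDR
(Benjamini–Hochberg) control are both available.

## Comparator: SKAT-like linear score test

The same gene is tested with a weighted linear-kernel variance-
component score statistic Q = r'Kr, where r are the OLS residuals of Y
on the covariate design (intercept-only by default) and
K = G·diag(w_k)·G' with w_k the squared Beta(1, 25) density of the MAF
— the standard convention that boosts rare variants; shapes are
configurable, and (1,1) gives a flat burden-style kernel.  The binary
cluster label is treated as a continuous response ("linear" variant; a
deliberate preservation of how the comparator is normally run in this
setting).  Under the null Q ~ σ²Σλ_i χ²₁ with λ_i the eigenvalues of
PKP (P the residual-maker) and σ² estimated from the residuals.  The
default p-value inverts the characteristic function numerically
(Imhof's integral), which is accurate across the whole unit interval;
Liu-type moment matching is kept as the cheap alternative
(`method="liu"`) — it is adequate for small p but visibly rough in the
left tail (p near 1 clumps), which the test suite quantifies against
permutations.  Analytic failures never drop a gene silently: they fall
back to a seeded permutation p with a warning, and the screening
driver records an NA with a warning if even that fails.

## Synthetic data: what it emulates, what it does not

`simdata` stands in for a sequencing cohort with simulated
longitudinal traits.  Defaults are the package's stated world:

| parameter | default | rationale |
|---|---|---|
| n_subjects | 500 | mid-size cohort, comfortably above k·group-size floors |
| genes / SNPs per gene | 50 / 20 | "genes of tens of SNPs" |
| MAF law | Uniform(0.01, 0.05) | the rare window the screen analyses by default |
| time points | 3 | fixed exam design |
| covariates | age ~ U{30..80} yr, sex ~ Bern(0.5), medication ~ Bern(0.3) per exam, independent | simple documented laws; no generative detail to copy |
| trait scale | intercept 120 mmHg, age +0.3/yr, sex +2, medication −5, noise SD 5 mmHg | SBP-like magnitudes |
| effect_size | 2.0 mmHg per minor allele (per exam index under `slope`) | chosen a priori so the genetic trajectory SD (≈ effect × burden SD × profile norm) is comparable to the noise SD — a detectable, not overwhelming, signal |

Genotypes are Hardy–Weinberg (Binomial(2, p)) for **unrelated**
subjects; the cohorts this mimics contain pedigrees, but relatedness
mainly inflates p-values uniformly across genes and leaves rankings
and ROC comparisons intact, so it is out of scope.  No linkage
disequilibrium, no imputation uncertainty, no irregular visit times.
A causal gene's burden is the minor-allele count over its causal SNPs
(default: all SNPs with true MAF < 0.05; a seeded fraction is
configurable), and the effect enters the trait as
profile(t) × effect_size × burden with profile ∈ {1, 1, 1} (`level`),
{0, 1, 2} (`slope`) or {−1, 0, 1} (`crossing`).  The three effect
shapes are this package's taxonomy for "the variant changes the trait
pattern over time", not an empirical claim.  Consequently a green
power test establishes that the pipeline recovers rare-variant-driven
trajectory effects *of this generative form* in an unrelated HWE
cohort — nothing more.

All randomness derives from `SimConfig.seed` through named substreams
(genotypes / covariates / per-replicate noise), so identical configs
are bit-identical, replicates share genotypes and covariates while
re-drawing noise, and any replicate is regenerable in isolation.

## Numerical choices

* **Ward on dissimilarities.**  The linkage applies the Lance–Williams
  Ward update directly to the supplied distances (squared internally,
  heights reported on the raw-distance scale — the `ward.D2`
  convention, matching scipy on Euclidean input).  Merge ties — common
  in genotype data, where subjects with identical rare-variant
  profiles sit at distance exactly 0 — are broken deterministically by
  the lexicographically smallest (min id, max id) pair, so results are
  platform-stable.  Tree cutting undoes the last k−1 merges following
  the merge *order*, never the heights, which makes it immune to the
  ~1e−13 height noise that tied merges leave behind.
* **Folding.**  Dosages are rounded half-up to {0,1,2} before scoring
  (the score table is defined on genotypes only); MAF is computed from
  rounded genotypes and columns with frequency > 0.5 are recoded
  g → 2−g.  Monomorphic columns are excluded (the table divides by p
  and 1−p); missing dosages are imputed to the modal genotype with a
  warning.  MAF window bounds are inclusive on both ends.  Observed
  MAFs are recomputed whenever the subject set changes.
* **Degenerate cases.**  Constant Y makes I undefined (error);
  zero within-group variance makes F infinite (warned, smallest
  positive p); an all-identical trajectory panel still yields two
  nonempty phenotype groups, flagged degenerate; a gene with no SNPs
  in the MAF window is skipped with a warning, never silently.
* **Permutation floor.**  p_perm ≥ 1/(B+1) by construction; B ≥ 100
  enforced.
* **ROC conventions.**  Scores are p-values (smaller = claimed
  earlier); tied scores are claimed together; failed genes (NA) rank
  last and the count is the caller's to report.  Replicate averaging
  is vertical (mean tpr on a fixed fpr grid of step 0.01, linear
  interpolation); the average curve's AUC is its own trapezoid area,
  which lies between the per-replicate extremes.  AUC comparison drops
  zero differences, uses the exact signed-rank null up to 25 nonzero
  pairs and the normal approximation above.

## Known limitations

* The phenotype summary is a hard 2-group split; borderline
  trajectories carry no uncertainty into the association stage.
* Asymptotic ANOVA p-values ignore relatedness; use permutations for
  real cohorts.
* The genotype-side clustering is recomputed per MAF window; there is
  no incremental update.
* The SKAT-like comparator is a linear (Gaussian) score test on a
  binary label, as is conventional in this setting, not a
  small-sample-adjusted binary SKAT, and no SKAT-O/burden variants are
  provided.
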
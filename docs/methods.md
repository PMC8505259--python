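# Methods

`polypgas` implements a triangulation strategy for finding common variants
associated with polytoxicomania (use of ≥3 illicit drug classes; caffeine
never counts) in a deeply phenotyped schizophrenia case/control cohort,
together with the genotype QC and environmental-risk statistics that
surround it. Because the individual-level data that motivated the design
are protected, the package ships a synthetic cohort generator that
reproduces the statistical structure the analysis assumes; every procedure
is exercised and calibrated against that generator.

## The triangulation (multiple GWAS–PGAS)

Six case/control logistic GWAS are run over one cohort:

* **Set 1 (GWAS 1–4)** — four polytoxicomania contrasts with mildly varied
  phenotype definitions: preadult polytox patients vs non-polytox
  patients + healthy (GWAS1); lifetime polytox vs the same controls
  (GWAS2); GWAS1 with drug-naive controls (GWAS3); case threshold raised
  to ≥4 classes (GWAS4). The published per-GWAS definitions live in a
  display item that is not fully public; this grid is an explicit,
  configurable emulation, and non-polytoxicomania control filters are
  applied to patient and healthy pools alike.
* **Set 2 (GWAS 5–6)** — disease-only contrasts: non-polytox patients vs
  non-polytox healthy (GWAS5) and all patients vs all healthy (GWAS6).

A SNP enters the final polytoxicomania set iff

1. its clump-index p-value is `< alpha_poly` (default 0.01) in **all** of
   GWAS 1–4,
2. its clump contains at least one other SNP at `p < alpha_neighbor`
   (default 0.05) in **each** of GWAS 1–4 (LD-neighbor support; singleton
   clumps fail this by default, `require_neighbor=False` disables it),
3. its p-value is `>= alpha_disease` (default 0.05) in **both** GWAS 5
   and 6 (the subtraction: anything disease-associated is removed).

Clumping is greedy: the unassigned SNP with the smallest p ≤ 0.01 becomes
an index (ties by chromosome, then position); unassigned SNPs within
250 kb at r² ≥ 0.5 join its clump. Clumping is anchored on GWAS1 by
default (the anchor is configurable; which GWAS anchored the published
clumping is not stated). "LD neighbors" are read as same-clump members.
Neighbor support is required in all four set-1 GWAS; requiring it in only
one is a weaker reading of the published criterion and can be emulated by
evaluating `neighbor_support` per contrast.

The report also carries the raw intersection (no clumping or neighbor
criterion — the analogue of a pre-clump SNP count), per-GWAS significant
sets at 0.05, their 6×6 Jaccard matrix (two empty sets are defined as
similarity 1) and exclusive UpSet-style intersection counts, which
partition the union by construction.

SNPs with an undefined p-value (monomorphic, separated or non-converged
fits) in any contrast are never candidates; they are flagged, not silently
assigned p = 1.

## Association models

Per-SNP tests are additive-dosage logistic regressions with sex and the
first 10 principal components as covariates, reporting Wald p-values (the
PLINK default; the gene-based test uses likelihood ratios instead). All
SNP models share the covariate block, so Newton/IRLS is batched across
SNPs; missing genotypes enter as zero IRLS weights (that sample is dropped
for that SNP only). Agreement with per-SNP maximum-likelihood fits
(statsmodels) is at the 1e-6 level; batching exists purely for speed
(6 contrasts × 5,000 SNPs × ~4,000 samples in well under a minute on one
core). Separation is flagged (|log-OR| > 15 or unbounded SE) rather than
penalised, keeping the estimator standard.

The gene-based test is a principal-component regression: PCs of the
standardized gene SNP submatrix are retained up to 99.9% of variance and
tested jointly by a likelihood-ratio χ² (df = retained PCs) against the
covariate-only model. SNP-to-gene mapping uses ±10 kb flanks; annotation
intervals follow BED conventions (0-based half-open), SNP positions are
1-based and converted explicitly, so a SNP exactly 10,000 bp from a gene
edge maps and one at 10,001 bp does not.

## Genotype and sample QC

Fixed order, survivors reported per stage: variant filters → LD pruning →
relatedness → PCA → ancestry outliers → PCA recomputed on survivors.

* **Variant filters.** MAF > 0.05 and exact conditional Hardy–Weinberg
  p > 0.001, both strict inequalities matching the printed thresholds. The
  HWE test conditions on allele counts and sums probabilities of
  heterozygote counts no more probable than the observed one; monomorphic
  variants return p = 1 by convention. The implementation evaluates the
  full conditional distribution with log-gamma arithmetic and matches an
  exact rational-arithmetic enumeration to < 1e-12 for all n ≤ 50.
* **LD pruning.** Greedy sliding windows (250 kb, step 5, remove one of
  any pair with r² > 0.5, keeping the higher-MAF member; tie keeps the
  lower index), with long-range-LD exclude regions (BED, empty by default
  for synthetic data) removed first.
* **Relatedness.** PLINK-style method-of-moments PI_HAT
  (P(IBD=2) + P(IBD=1)/2) from IBS counts, with finite-sample-corrected
  expectations (falling-factorial unbiased estimators of the frequency
  monomials). Pairs with PI_HAT > 0.185 are resolved greedily by
  descending PI_HAT: patient kept over healthy control, same-label pairs
  lose a uniformly random member under the run seed. PI_HAT is estimated
  on the pruned marker set; an optional stricter re-prune
  (`relatedness_r2_max`) exists but is off by default — measurements on
  the synthetic panels showed the estimator's precision is bounded by the
  number of independent LD blocks, so discarding markers only adds noise.
* **Ancestry outliers.** Samples beyond 3 SD on PC1 or 5 SD on PC2
  (strict) are removed; PCs are then recomputed on the survivors and those
  recomputed PCs feed association. Whether the original analysis recomputed
  PCs after outlier removal is unstated; recomputing avoids leakage from
  excluded outliers.
* **PCA.** Standardized (mean-imputed, centred, unit-variance) genotypes,
  top components via Lanczos SVD run to machine precision with a fixed
  start vector; each component's sign is fixed by making its
  largest-|loading| entry positive, so results are deterministic and
  equivariant under sample permutation.

## The synthetic cohort generator

The generator emulates the *structure* of the motivating study — it is an
emulation for testing, not a claim about any real cohort.

* **Genotypes.** Biallelic autosomal SNPs on synthetic chromosomes
  (1-based positions, 1 kb spacing; LD blocks never straddle chromosome
  ends). Ancestral frequencies are drawn per LD block from `maf_range`
  (uniform) with small per-SNP jitter — SNPs in strong LD necessarily have
  similar frequencies, and block-level frequencies are what makes the LD
  parameter an effective r² dial. Subpopulation frequencies follow the
  Balding–Nichols model (default two subpopulations, Fst 0.005, a
  realistic within-country differentiation). Within a block, haplotypes
  follow a latent-uniform copying chain: SNP j reuses SNP j−1's latent
  uniform with probability `ld_decay` (default 0.85, giving adjacent-SNP
  r² ≈ 0.6–0.7 and 2–4 informative clump neighbors per planted locus,
  matching the working hypothesis that true signals have LD support).
  Copying preserves every SNP's marginal frequency, so Hardy–Weinberg
  holds within subpopulations for any `ld_decay`. Missingness is MCAR
  (default 0.2%).
* **Phenotypes.** Sex ~ Bernoulli(0.66 male). Six binary environmental
  risks at the reference prevalences (urbanicity 43.1%, cannabis 38.3%,
  alcohol 20.0%, physical abuse 16.5%, sexual abuse 13.3%, migration
  10.8%). Disease status: a logistic-noise liability over disease and
  pleiotropic loci, with the top `n_patients` samples declared patients —
  case/control ascertainment under a logistic model preserves the planted
  log-odds ratios. Drug use: each of 8 classes is used iff a shared
  liability (planted polytox/pleiotropic score + `env_effect` × risk count
  + per-class standard-normal noise) exceeds a common threshold; the
  threshold is solved so that the lifetime polytoxicomania rate is 21%
  (the reference cohort's share of ≥3-class users among phenotyped
  patients). Onset per used class is preadult with probability 0.8, else
  adult. Groups: preadult polytox = ≥3 preadult classes; adult = ≥3
  lifetime but not preadult; else non-polytox. Drug use is simulated
  independently of diagnosis so polytox-specific loci carry no disease
  signal by construction.
* **Effect calibration.** The ≥3-of-8 threshold construction sharpens the
  liability-to-status link, so a liability coefficient of log(OR) would
  not produce a marginal allelic OR of OR on polytoxicomania status. Each
  planted coefficient is therefore calibrated numerically (fixed point
  over loci, re-solving the class threshold each round) so that the
  implied marginal allelic odds ratio on lifetime polytoxicomania equals
  the configured value; dosages are centred so the liability scale stays
  anchored for any number of planted loci. Re-estimated ORs from simulated
  cohorts cover the target (checked at OR 2.0, MAF 0.3).
* **What it does not emulate.** Realistic recombination maps, phased
  haplotype sharing, drug-use/diagnosis dependence, missingness that is
  informative, X-chromosome inheritance, or real minor-allele-frequency
  spectra. Passing tests therefore demonstrate the *procedure's*
  selectivity and calibration under the assumed structure, not performance
  on real genotype data. The generator also has no true related pairs; all
  relatedness exclusions in simulated runs are estimator noise.

## Environmental-risk statistics

* **Stratified counts** (consumption group × number-of-risks stratum ×
  risk factor) with totals summed over all cells; the zero-risk stratum
  contributes no exposures by construction. The printed reference table is
  shipped as data and its Total row (cannabis 471, alcohol 246, urbanicity
  524, migration 133, physical abuse 203, sexual abuse 164) is reproduced
  exactly by `table_totals`. Percentage denominators are not printed in
  the source table, so only counts are treated as reproducible.
* **Trend tests.** Cochran–Armitage (2×K, default scores 0..K−1) and
  Jonckheere–Terpstra (sum of pairwise Mann–Whitney counts over ordered
  group pairs, ties ½), each with an asymptotic normal p (tie-corrected
  for JT) and a permutation p with B = 20,000 default, the add-one
  estimator (1 + #exceedances)/(B + 1), and a mandatory seed. CA
  permutations resample stratum case counts from the margin-conditioned
  multivariate hypergeometric; JT permutes labels with an O(B·n·K)
  cumulative-count scheme. CA with two strata reduces exactly to the
  two-proportion z-test; JT with two groups reduces to Mann–Whitney U.
* **Odds ratios.** Cross-product estimate with a Wald log-scale CI when
  all cells are positive; any zero cell switches to conditional-exact
  inference under the noncentral hypergeometric likelihood (conditional
  MLE, exact tail-inversion CI), reporting 0/+∞ bounds when the observed
  table sits on the support boundary — the "[50.8–∞]" reporting shape.
  The exact conditional method is the standard open equivalent of
  exact logistic regression for a single 2×2 margin.
* **Collinearity.** VIF_j = 1/(1−R²_j) per risk predictor with a default
  acceptance bound of 1.2; perfectly collinear predictors report +∞.
* **Chi-square** without continuity correction by default (a flag enables
  Yates); Fisher's exact test is two-sided by summing hypergeometric
  probabilities no larger than the observed table's.

## Numerical and degenerate-input conventions

* All probability thresholds are strict in the direction printed
  ("> 0.05", "> 0.001", "> 0.185"; subtraction keeps `p >= 0.05`).
* p-values are clipped into (0, 1]; permutation p-values live in
  [1/(B+1), 1].
* Monomorphic variants: MAF 0 (filtered), HWE p = 1, association flagged
  rather than tested, r² undefined (NaN).
* Greedy tie-breaks are fixed and documented: clump indices by
  (p, chromosome, position); pruning keeps the higher-MAF member, ties the
  lower index; relatedness pairs by descending PI_HAT then index.
* Fixed seed ⇒ byte-identical cohorts, files and reports; all randomness
  flows from `numpy.random.default_rng` seeded from the run seed.

## Desk-scale study conditions

Simulation-based suites run at 2,000 patients + 2,000 controls over
5,000 SNPs (ten seeds), the largest size that keeps the full test suite
comfortably within a routine CI run; the acceptance script uses three
seeds per suite for the same reason. A 5,000-SNP block-LD panel carries
only ~250 independent loci, so the PI_HAT noise floor sits near 0.03–0.04
and the printed 0.185 threshold falsely excludes roughly a quarter of the
simulated (entirely unrelated) samples; all calibration and recovery
results below are measured under exactly these conditions, and the
remaining sample size (~3,000) carries the power. On real panels
(~100,000 pruned markers) the same estimator's noise is an order of
magnitude smaller and this over-exclusion disappears.

## Known limitations

* **Subtraction collider.** Conditioning both GWAS5 groups on
  non-polytoxicomania makes polytox-risk alleles anti-correlate with
  pleiotropic alleles inside the selected sample; since pleiotropic
  alleles predict diagnosis, true polytox loci acquire a small spurious
  disease-contrast signal and are occasionally (order 5% per locus at
  desk scale with pleiotropic ORs of 1.5) subtracted. This is a genuine
  property of the intersection-subtraction design under pleiotropy, not
  an implementation artifact; it grows with the pleiotropic effect sizes
  and with sample size.
* Planted effect sizes default to OR 2.0 for polytox-specific loci (the
  recovery benchmark) and OR 1.5 for disease-specific and pleiotropic
  loci — generous relative to real common-variant psychiatric
  architecture, chosen so that desk-scale disease contrasts flag them
  reliably (z > 5) while keeping the collider above small.
* PI_HAT at a few thousand markers cannot separate third-degree relatives
  from noise; the 0.185 threshold is only meaningful on large marker sets,
  which is why the generator plants no true relatives.
* The six-contrast grid is an emulation; with the real display-item
  definitions the `PhenotypeDefinition` grid should be replaced, not the
  code.
* Exact odds-ratio CIs use the conditional (central) inversion; mid-p or
  unconditional exact variants are not implemented.
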
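# polypgas

Triangulating the genetics of **polytoxicomania** — the use of three or
more illicit drug classes — in a deeply phenotyped schizophrenia
case/control cohort. Single GWAS in cohorts of a few thousand samples
cannot deliver genome-wide-significant hits for such a phenotype; the
strategy implemented here instead demands *consistency across several
mildly varied phenotype definitions* and *removes everything attributable
to the disease itself*.

Concretely, six logistic GWAS (additive dosage coding, sex + 10 principal
components as covariates) are run over one cohort. Four contrasts vary
the polytoxicomania definition (preadult vs lifetime onset, ≥3 vs ≥4 drug
classes, all non-polytox vs drug-naive controls); two contrast diagnosis
only. A SNP `j` (as the index of its LD clump) is retained iff

```
p_j < 0.01             in GWAS 1..4          (consistency)
min member p < 0.05    in GWAS 1..4          (LD-neighbor support)
p_j >= 0.05            in GWAS 5 and GWAS 6  (disease subtraction)
```

with greedy LD clumping (index p ≤ 0.01, r² ≥ 0.5, 250 kb). The package
also provides the surrounding machinery as first-class, tested components:

* `polypgas.synthio` — synthetic cohorts: Balding–Nichols stratification,
  block LD via a latent copying chain, liability-model drug-use phenotypes
  with planted polytox-specific / disease-specific / pleiotropic loci at
  calibrated allelic odds ratios, six environmental risks at published
  prevalences; PLINK text and binary filesets read and written natively.
* `polypgas.gqc` — variant QC (MAF > 0.05, exact Hardy–Weinberg
  p > 0.001), LD pruning, PLINK-style PI_HAT relatedness exclusion
  (> 0.185, patients prioritised), PCA and PC1/PC2 ancestry outliers
  (3/5 SD).
* `polypgas.assoc` — declarative phenotype contrasts, a batched logistic
  GWAS engine (statsmodels-exact, genome-scan fast), gene-based
  PC regression, ±10 kb SNP-to-gene mapping.
* `polypgas.pgas` — clumping, neighbor support, intersection–subtraction,
  Jaccard matrices, UpSet-style exclusive intersection counts, and the
  end-to-end seeded pipeline with truth-recovery scoring.
* `polypgas.riskstats` — consumption-group rules, stratified exposure
  tables, Cochran–Armitage and Jonckheere–Terpstra permutation trend
  tests (B = 20,000), odds ratios with conditional-exact zero-cell
  handling, VIF screening.

The model and its assumptions, all defaults, and known limitations are
documented in [docs/methods.md](docs/methods.md).

## Worked example

```python
import polypgas as pg

cfg = pg.SimConfig(
    n_patients=2000, n_controls=2000, n_snps=5000, seed=19,
    planted_loci=[pg.PlantedLocus("polytox", 0.3, 2.0)] * 2
    + [pg.PlantedLocus("disease", 0.3, 1.5)] * 2
    + [pg.PlantedLocus("pleiotropic", 0.3, 1.5)] * 2,
)
result = pg.run_pgas_pipeline(sim_config=cfg, seed=19)
print(result.report.final_snps)
print(result.report.truth_summary)
```

prints (exactly, for this seed; about a minute on one core):

```
['snp002140', 'snp002769', 'snp002771', 'snp002773', 'snp004909', 'snp004911', 'snp004914', 'snp004918']
{'n_polytox': 2, 'polytox_recovered': 2, 'polytox_in_final': 2,
 'n_disease': 2, 'disease_recovered': 0, 'disease_in_final': 0,
 'n_pleiotropic': 2, 'pleiotropic_recovered': 0, 'pleiotropic_in_final': 0,
 'pleiotropic_subtraction_violations': 0}
```

Both planted polytoxicomania loci (`snp002771`, `snp004911`) survive the
triangulation — along with their own clump/block LD neighbors — while the
disease-specific and pleiotropic loci are removed by the subtraction
against the two disease contrasts (`snp002140` is the one false positive
of this run). The
`examples/` directory holds one short script per capability (simulation,
QC, contrast GWAS, triangulation, risk statistics), each printing the
numbers it computes and what they mean. A thin CLI mirrors the pipeline:

```bash
polypgas simulate --config sim.yaml --seed 3 --out cohort
polypgas qc cohort --seed 3 --out qcres
polypgas gwas cohort --samples cohort.samples.tsv --seed 3 --out gw
polypgas pgas --results-prefix gw --prefix cohort --seed 3 --out report.json
polypgas risktable --samples cohort.samples.tsv --out risks
polypgas trend 190 160 100 40 10 40 100 160 --seed 1
```

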